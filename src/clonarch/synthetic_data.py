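"""Ground-truthed synthetic multi-zone cohorts.

Emulates the data a targeted multi-region sequencing study of early lung
lesions produces: a branched clone tree per lesion, truncal / shared-branch /
private mutations assigned to branches, per-zone clone mixtures diluted by
normal cells (tumor purity), distinct read-pair tallies for each zone and a
matched normal at panel depth, and droplet digital PCR partitions of mutant
templates in a wild-type background.

Every draw is taken from a named sub-stream of the single master seed
(stable hashing of (purpose, zone, locus, ...)), so outputs are reproducible
byte-for-byte and adding a zone or locus never perturbs existing draws.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ._util import substream
from .panel import GeneModel, sample_coding_snv, synthetic_panel

TALLY_COLUMNS = [
    "contig", "pos", "ref", "alt", "sample",
    "alt_distinct_pairs", "total_distinct_pairs",
]


class SimulationConfig(BaseModel):
    """All knobs of the generator; the seed is mandatory (no implicit entropy).

    Defaults mirror the study conditions this package targets: ~400x panel
    depth, >60% neoplastic cellularity after microdissection, ~20,000 droplets
    of ~1 nl per ddPCR well.
    """

    n_zones: int = Field(default=4, ge=1)
    n_truncal: int = Field(default=3, ge=0)
    n_branch: int = Field(default=4, ge=0)
    n_private: int = Field(default=5, ge=0)
    tumor_purity: float | list[float] = 0.6
    mean_depth: float = Field(default=400.0, ge=1)
    per_base_error: float = Field(default=0.001, ge=0.0, le=1.0)
    droplet_count: int = Field(default=20_000, ge=1)
    droplet_volume_nl: float = Field(default=1.0, gt=0)
    template_copies: int = Field(default=10_000, ge=0)
    n_germline_sites: int = Field(default=0, ge=0)
    random_seed: int

    @model_validator(mode="after")
    def _check_purity(self):
        purities = self.tumor_purity if isinstance(self.tumor_purity, list) else [self.tumor_purity]
        if isinstance(self.tumor_purity, list) and len(self.tumor_purity) != self.n_zones:
            raise ValueError("tumor_purity: per-zone list must have n_zones entries")
        for p in purities:
            if not 0.0 <= p <= 1.0:
                raise ValueError("tumor_purity: purities must lie in [0, 1]")
        return self

    def purity(self, zone_index: int) -> float:
        if isinstance(self.tumor_purity, list):
            return self.tumor_purity[zone_index]
        return self.tumor_purity

    @property
    def zones(self) -> list[str]:
        return [f"Z{i + 1}" for i in range(self.n_zones)]


@dataclass(frozen=True)
class VariantSite:
    """Genomic identity of one simulated mutation."""

    gene: str
    contig: str
    pos: int
    ref: str
    alt: str
    consequence: str


@dataclass
class CloneTree:
    """Branched clone genealogy plus per-zone clone mixing fractions.

    ``zone_composition[zone][clone]`` is the fraction of *all* cells in the
    zone belonging to that clone; the remainder to 1 is normal contamination.
    A mutation on a branch is carried by that clone and every descendant.
    """

    nodes: list[str]
    parent: dict[str, str | None]
    mutations_on_branch: dict[str, frozenset[str]]
    zone_composition: dict[str, dict[str, float]]

    def validate(self) -> None:
        roots = [n for n in self.nodes if self.parent.get(n) is None]
        if len(roots) != 1:
            raise ValueError(f"clone tree must have exactly one root, found {roots}")
        for node in self.nodes:
            seen, cur = set(), node
            while cur is not None:
                if cur in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(cur)
                cur = self.parent.get(cur)
        assigned: set[str] = set()
        for muts in self.mutations_on_branch.values():
            if assigned & muts:
                raise ValueError("a mutation is assigned to more than one branch")
            assigned |= muts
        for zone, comp in self.zone_composition.items():
            total = sum(comp.values())
            if not -1e-9 <= total <= 1 + 1e-9:
                raise ValueError(f"zone {zone}: clone fractions sum to {total}, outside [0, 1]")

    def subtree(self, clone: str) -> set[str]:
        out = {clone}
        changed = True
        while changed:
            changed = False
            for node in self.nodes:
                if node not in out and self.parent.get(node) in out:
                    out.add(node)
                    changed = True
        return out

    def mutation_clone(self, mutation: str) -> str:
        for clone, muts in self.mutations_on_branch.items():
            if mutation in muts:
                return clone
        raise KeyError(mutation)

    def mutations(self) -> list[str]:
        return sorted(m for muts in self.mutations_on_branch.values() for m in muts)


@dataclass
class GroundTruth:
    """Per-mutation truth used to score the downstream analysis."""

    sites: dict[str, VariantSite]
    presence: dict[str, frozenset[str]]          # mutation -> zones carrying it
    cell_fraction: dict[str, dict[str, float]]   # within-tumor fraction per zone
    fluid_fraction_pct: dict[str, float]         # true circulating-DNA abundance
    germline_sites: list[VariantSite] = field(default_factory=list)

    def validate(self, tree: CloneTree) -> None:
        for mut, zones in self.presence.items():
            carriers = tree.subtree(tree.mutation_clone(mut))
            for zone in zones:
                comp = tree.zone_composition[zone]
                if not any(comp.get(c, 0.0) > 0 for c in carriers):
                    raise ValueError(f"{mut} marked present in {zone} but no carrier clone is mixed in")
        for mut, pct in self.fluid_fraction_pct.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{mut}: fluid fraction {pct} outside [0, 100]")


# ----------------------------------------------------------------------
# clone tree + truth
# ----------------------------------------------------------------------

def simulate_clone_tree(config: SimulationConfig) -> CloneTree:
    """Build a branched clone tree with per-zone mixtures.

    Topology: a truncal clone C0 at the root; zones split into two sides each
    headed by an internal clone (B1, B2) carrying shared-branch mutations;
    one leaf clone per zone carrying its private mutations.  With a single
    zone the tree degenerates to a chain.  Per-zone mixing weights along the
    root-to-leaf path are drawn from the seed, each at least 20% of the tumor
    compartment so every simulated mutation is clonally substantial.
    """
    zones = config.zones
    n = config.n_zones
    nodes = ["C0"]
    parent: dict[str, str | None] = {"C0": None}
    side_of: dict[str, str] = {}

    internals: list[str] = []
    if n >= 2:
        split = (n + 1) // 2
        for side, members in enumerate(([zones[:split], zones[split:]])):
            name = f"B{side + 1}"
            internals.append(name)
            nodes.append(name)
            parent[name] = "C0"
            for z in members:
                side_of[z] = name
    else:
        side_of[zones[0]] = "C0"

    leaf_of: dict[str, str] = {}
    for i, z in enumerate(zones):
        leaf = f"L{i + 1}"
        leaf_of[z] = leaf
        nodes.append(leaf)
        parent[leaf] = side_of[z]

    muts: dict[str, set[str]] = {c: set() for c in nodes}
    counter = 0

    def new_mut(clone: str) -> None:
        nonlocal counter
        muts[clone].add(f"mut_{counter:03d}")
        counter += 1

    for _ in range(config.n_truncal):
        new_mut("C0")
    branch_targets = internals if internals else [leaf_of[zones[0]]]
    for k in range(config.n_branch):
        new_mut(branch_targets[k % len(branch_targets)])
    for k in range(config.n_private):
        new_mut(leaf_of[zones[k % n]])

    composition: dict[str, dict[str, float]] = {}
    for i, z in enumerate(zones):
        path = ["C0"]
        if side_of[z] != "C0":
            path.append(side_of[z])
        path.append(leaf_of[z])
        rng = substream(config.random_seed, "composition", z)
        u = rng.uniform(0.25, 0.5, size=len(path))
        w = u / u.sum() * config.purity(i)
        composition[z] = {clone: float(frac) for clone, frac in zip(path, w)}

    tree = CloneTree(
        nodes=nodes,
        parent=parent,
        mutations_on_branch={c: frozenset(m) for c, m in muts.items()},
        zone_composition=composition,
    )
    tree.validate()
    return tree


def derive_ground_truth(
    tree: CloneTree,
    config: SimulationConfig,
    panel: GeneModel | None = None,
    reference: dict[str, str] | None = None,
) -> GroundTruth:
    """Attach genomic sites and truth tables to a simulated clone tree.

    Each mutation is placed at a random non-silent coding SNV site of the
    synthetic panel.  True fluid fractional abundances are drawn log-uniform
    in [0.03%, 1%], the range reported for mutant circulating DNA in plasma
    and sputum of early-lesion patients.
    """
    if panel is None or reference is None:
        panel, reference = synthetic_panel(config.random_seed)
    site_rng = random.Random(int(substream(config.random_seed, "sites").integers(2**31)))
    sites: dict[str, VariantSite] = {}
    used: set[tuple[str, int]] = set()
    for mut in tree.mutations():
        while True:
            gene, contig, pos, ref, alt, csq = sample_coding_snv(panel, reference, site_rng)
            if (contig, pos) not in used:
                used.add((contig, pos))
                break
        sites[mut] = VariantSite(gene, contig, pos, ref, alt, csq)

    presence: dict[str, frozenset[str]] = {}
    cell_fraction: dict[str, dict[str, float]] = {}
    for mut in tree.mutations():
        carriers = tree.subtree(tree.mutation_clone(mut))
        zones, fractions = [], {}
        for zone, comp in tree.zone_composition.items():
            tumor = sum(comp.values())
            carried = sum(f for c, f in comp.items() if c in carriers)
            if carried > 0:
                zones.append(zone)
                fractions[zone] = carried / tumor if tumor else 0.0
        presence[mut] = frozenset(zones)
        cell_fraction[mut] = fractions

    fluid_rng = substream(config.random_seed, "fluid")
    lo, hi = np.log(0.03), np.log(1.0)
    fluid = {
        mut: float(np.exp(fluid_rng.uniform(lo, hi)))
        for mut in tree.mutations()
    }

    germline: list[VariantSite] = []
    for k in range(config.n_germline_sites):
        g_rng = random.Random(int(substream(config.random_seed, "germline", k).integers(2**31)))
        while True:
            gene, contig, pos, ref, alt, csq = sample_coding_snv(panel, reference, g_rng)
            if (contig, pos) not in used:
                used.add((contig, pos))
                break
        germline.append(VariantSite(gene, contig, pos, ref, alt, csq))

    truth = GroundTruth(
        sites=sites,
        presence=presence,
        cell_fraction=cell_fraction,
        fluid_fraction_pct=fluid,
        germline_sites=germline,
    )
    truth.validate(tree)
    return truth


# ----------------------------------------------------------------------
# read-pair tallies
# ----------------------------------------------------------------------

def _binomial_site(rng: np.random.Generator, mean_depth: float, p: float) -> tuple[int, int]:
    depth = int(rng.poisson(mean_depth))
    depth = max(depth, 1)
    alt = int(rng.binomial(depth, min(max(p, 0.0), 1.0)))
    return alt, depth


def simulate_tallies(
    tree: CloneTree,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Distinct read-pair tallies per zone plus one matched-normal table.

    At a mutated locus the expected alternate fraction is
    purity x cellular fraction x 0.5 (heterozygous single-copy model) plus the
    per-base error; elsewhere, and in the normal, alternates arise from error
    alone.  Depth is Poisson around ``mean_depth``; alternate counts are
    binomial.  Germline heterozygous sites, when configured, appear at ~50%
    in every sample.
    """
    zones = config.zones
    err = config.per_base_error
    tumor_tables: dict[str, pd.DataFrame] = {}
    all_sites = list(truth.sites.items())

    for i, zone in enumerate(zones):
        if zone not in tree.zone_composition:
            raise KeyError(f"zone {zone} absent from clone tree composition")
        purity = config.purity(i)
        rows = []
        for mut, site in all_sites:
            cf = truth.cell_fraction[mut].get(zone, 0.0) if zone in truth.presence[mut] else 0.0
            p = purity * cf * 0.5 + err
            rng = substream(config.random_seed, "tally", zone, site.contig, site.pos)
            alt, depth = _binomial_site(rng, config.mean_depth, p)
            rows.append((site.contig, site.pos, site.ref, site.alt, zone, alt, depth))
        for site in truth.germline_sites:
            rng = substream(config.random_seed, "tally", zone, site.contig, site.pos)
            alt, depth = _binomial_site(rng, config.mean_depth, 0.5)
            rows.append((site.contig, site.pos, site.ref, site.alt, zone, alt, depth))
        tumor_tables[zone] = pd.DataFrame(rows, columns=TALLY_COLUMNS)

    rows = []
    for mut, site in all_sites:
        rng = substream(config.random_seed, "tally", "normal", site.contig, site.pos)
        alt, depth = _binomial_site(rng, config.mean_depth, err)
        rows.append((site.contig, site.pos, site.ref, site.alt, "normal", alt, depth))
    for site in truth.germline_sites:
        rng = substream(config.random_seed, "tally", "normal", site.contig, site.pos)
        alt, depth = _binomial_site(rng, config.mean_depth, 0.5)
        rows.append((site.contig, site.pos, site.ref, site.alt, "normal", alt, depth))
    normal_table = pd.DataFrame(rows, columns=TALLY_COLUMNS)
    return tumor_tables, normal_table


def simulate_true_snvs(
    n: int,
    mean_depth: float,
    fraction_range_pct: tuple[float, float],
    per_base_error: float,
    seed: int,
) -> pd.DataFrame:
    """Tumor/normal tally pairs for ``n`` true somatic SNVs.

    True tumor alternate fractions are drawn uniformly in the given percent
    range; the matched normal carries only sequencing error.  Returns one row
    per variant with tumor and normal counts side by side plus the true
    fraction, for caller-sensitivity studies.
    """
    lo, hi = fraction_range_pct
    rows = []
    for k in range(n):
        rng = substream(seed, "snv", k)
        frac = rng.uniform(lo, hi) / 100.0
        t_alt, t_depth = _binomial_site(rng, mean_depth, frac)
        n_alt, n_depth = _binomial_site(rng, mean_depth, per_base_error)
        rows.append(("ctg_sim", k + 1, "G", "A", frac * 100, t_alt, t_depth, n_alt, n_depth))
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt", "true_fraction_pct",
            "tumor_alt", "tumor_total", "normal_alt", "normal_total",
        ],
    )


# ----------------------------------------------------------------------
# droplets
# ----------------------------------------------------------------------

def simulate_droplets(true_fraction_pct: float, config: SimulationConfig, well: int = 0):
    """Partition mutant and wild-type templates into droplets for one well.

    The mutant share of ``template_copies`` is set by ``true_fraction_pct``;
    each template lands in a uniformly random droplet and a droplet is
    positive for a channel iff at least one template of that channel landed
    in it.  Returns a :class:`~clonarch.ddpcr_quant.DropletCount`.
    """
    from .ddpcr_quant import DropletCount

    if not 0.0 <= true_fraction_pct <= 100.0:
        raise ValueError("true_fraction_pct must lie in [0, 100]")
    n = config.droplet_count
    m = int(round(config.template_copies * true_fraction_pct / 100.0))
    w = config.template_copies - m
    rng = substream(config.random_seed, "droplets", well, repr(true_fraction_pct))
    k_m = len(np.unique(rng.integers(0, n, size=m))) if m else 0
    k_w = len(np.unique(rng.integers(0, n, size=w))) if w else 0
    return DropletCount(
        well=f"well_{well}",
        mutation_id="sim",
        droplets_total=n,
        mutant_positive=k_m,
        wildtype_positive=k_w,
        droplet_volume_nl=config.droplet_volume_nl,
    )
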
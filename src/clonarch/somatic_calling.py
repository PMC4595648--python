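"""Matched tumor/normal somatic mutation calling for targeted panels.

The caller reproduces a conservative pipeline-style rule set operating on
*distinct read pairs* (deduplicated paired fragments):

  i.   distinct read pairs carrying the alternate allele in the tumor reach a
       minimum count (default 2, i.e. the mutation is seen in pairs, plural);
  ii.  those pairs are at least 2% of all distinct read pairs at the locus;
  iii. the mismatched base is in at most 1% of the matched-normal reads and
       the site is not in a common-germline exclusion database;
  iv.  the position is covered in both the tumor and the normal.

Upstream, an alignment filter removes quality-failed, unpaired and poorly
mapped observations, and a base-quality filter keeps only bases with phred
strictly above 30 (tumor) / 20 (normal).  Downstream, accepted calls are
classified by coding consequence and silent or intronic changes are dropped;
fractional abundance is 100 x alternate / total distinct pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from ._util import round_half_up
from .panel import GeneModel

REJECTION_CODES = ("i", "ii", "iii", "iv", "germline", "quality", "consequence", "off-target")


@dataclass(frozen=True)
class ReadPairObservation:
    """One read pair's vote at one locus, prior to tallying."""

    contig: str
    pos: int
    ref: str
    allele: str
    is_paired: bool
    is_quality_pass: bool
    mapping_quality: int
    min_phred: int           # minimum base phred across the variant site
    fragment: str            # fragment signature (endpoints) for distinctness

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if self.min_phred < 0:
            raise ValueError("phred must be >= 0")


@dataclass(frozen=True)
class AlleleTally:
    contig: str
    pos: int
    ref: str
    alt: str
    sample_role: str         # "tumor" | "normal"
    alt_pairs: int           # distinct read pairs carrying the alternate
    total_pairs: int         # all distinct read pairs at the locus

    def __post_init__(self):
        if not 0 <= self.alt_pairs <= self.total_pairs:
            raise ValueError("need 0 <= alt_pairs <= total_pairs")
        if not (self.ref and self.alt and set(self.ref + self.alt) <= set("ACGT-")):
            raise ValueError(f"alleles must be non-empty strings over ACGT- ({self.ref}>{self.alt})")

    @property
    def fraction(self) -> float:
        return self.alt_pairs / self.total_pairs if self.total_pairs else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SomaticCall:
    contig: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str | None = None
    fractional_abundance: float = 0.0   # percent, full precision
    status: str = "accepted"            # "accepted" | "rejected"
    reason: str | None = None           # rejection rule code

    def __post_init__(self):
        if self.status == "accepted" and self.consequence in ("silent", "intronic"):
            raise ValueError("accepted calls can never be silent or intronic")
        if not 0.0 <= self.fractional_abundance <= 100.0:
            raise ValueError("fractional abundance must lie in [0, 100]")

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def mutation_key(self) -> tuple[str | None, str, int, str, str]:
        """Identity key used by the zone-presence matrix: (gene, locus, ref, alt)."""
        return (self.gene, self.contig, self.pos, self.ref, self.alt)


class GermlineDB:
    """Common-germline exclusion list keyed by (contig, pos, alt)."""

    def __init__(self, records: Iterable[tuple[str, int, str]] = ()):
        self._records: set[tuple[str, int, str]] = set()
        for contig, pos, alt in records:
            self.add(contig, pos, alt)

    def add(self, contig: str, pos: int, alt: str) -> None:
        self._records.add((contig, int(pos), alt))

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        contig, pos, alt = key
        return (contig, int(pos), alt) in self._records

    def __len__(self) -> int:
        return len(self._records)


@dataclass(frozen=True)
class CallerThresholds:
    """Filter settings; defaults are the conventional strict panel settings."""

    tumor_phred_min: int = 30        # strict: phred must exceed this
    normal_phred_min: int = 20
    tumor_fraction_min: float = 0.02
    normal_fraction_max: float = 0.01
    min_alt_pairs: int = 2
    min_mapping_quality: int = 20

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction_min <= 1.0 or not 0.0 <= self.normal_fraction_max <= 1.0:
            raise ValueError("fraction thresholds must lie in [0, 1]")
        if self.tumor_phred_min < 0 or self.normal_phred_min < 0:
            raise ValueError("phred thresholds must be >= 0")


DEFAULT_THRESHOLDS = CallerThresholds()


# ----------------------------------------------------------------------
# tallying raw observations
# ----------------------------------------------------------------------

def tally_observations(
    observations: Iterable[ReadPairObservation],
    role: str,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
) -> list[AlleleTally]:
    """Collapse read-pair observations into per-(locus, alt) tallies.

    Applies the alignment filter (paired, quality-pass, mapping quality) and
    the role-specific base-quality filter, then counts each distinct fragment
    signature once per locus; where duplicate observations of one fragment
    disagree, the highest-phred observation wins.  Totals count all surviving
    distinct pairs at the locus regardless of allele.
    """
    phred_min = thresholds.tumor_phred_min if role == "tumor" else thresholds.normal_phred_min
    best: dict[tuple[str, int, str], dict[str, ReadPairObservation]] = {}
    for obs in observations:
        if not obs.is_paired or not obs.is_quality_pass:
            continue
        if obs.mapping_quality < thresholds.min_mapping_quality:
            continue
        if obs.min_phred <= phred_min:
            continue
        locus = (obs.contig, obs.pos, obs.ref)
        frags = best.setdefault(locus, {})
        prev = frags.get(obs.fragment)
        if prev is None or obs.min_phred > prev.min_phred:
            frags[obs.fragment] = obs
    tallies: list[AlleleTally] = []
    for (contig, pos, ref), frags in sorted(best.items()):
        total = len(frags)
        alt_counts: dict[str, int] = {}
        for obs in frags.values():
            if obs.allele != ref:
                alt_counts[obs.allele] = alt_counts.get(obs.allele, 0) + 1
        for alt, count in sorted(alt_counts.items()):
            tallies.append(AlleleTally(contig, pos, ref, alt, role, count, total))
    return tallies


# ----------------------------------------------------------------------
# the candidate-mutation rules
# ----------------------------------------------------------------------

def call_somatic(
    tumor: AlleleTally,
    normal: AlleleTally,
    db: GermlineDB | None = None,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
) -> SomaticCall:
    """Apply rules i-iv to one matched tumor/normal tally pair.

    Acceptance requires every rule to hold.  The recorded rejection reason
    follows the convention that the headline 2% fraction rule (ii) is
    reported ahead of the supporting-pair count rule (i) when both fail,
    then iii, germline and iv.  Fractional abundance (percent of tumor
    distinct pairs) is recorded at full precision.
    """
    if tumor.key != normal.key:
        raise ValueError(f"tumor/normal tallies disagree on locus/allele: {tumor.key} vs {normal.key}")
    reason = None
    if tumor.total_pairs == 0 or tumor.fraction < thresholds.tumor_fraction_min:
        reason = "ii"
    elif tumor.alt_pairs < thresholds.min_alt_pairs:
        reason = "i"
    elif normal.total_pairs > 0 and normal.fraction > thresholds.normal_fraction_max:
        reason = "iii"
    elif db is not None and (tumor.contig, tumor.pos, tumor.alt) in db:
        reason = "germline"
    elif tumor.total_pairs == 0 or normal.total_pairs == 0:
        reason = "iv"
    fa = 100.0 * tumor.fraction
    if reason is not None:
        return SomaticCall(
            tumor.contig, tumor.pos, tumor.ref, tumor.alt,
            fractional_abundance=fa, status="rejected", reason=reason,
        )
    return SomaticCall(tumor.contig, tumor.pos, tumor.ref, tumor.alt, fractional_abundance=fa)


def annotate_consequence(call: SomaticCall, model: GeneModel, reference) -> SomaticCall:
    """Attach gene and consequence class; drop silent/intronic/off-target calls."""
    if not call.accepted:
        return call
    gene, csq = model.classify(call.contig, call.pos, call.ref, call.alt, reference)
    if csq == "off-target":
        return replace(call, status="rejected", reason="off-target")
    if csq in ("silent", "intronic"):
        return replace(call, gene=gene, consequence=csq, status="rejected", reason="consequence")
    return replace(call, gene=gene, consequence=csq)


def fractional_abundance(tally: AlleleTally) -> float:
    """Percent of distinct pairs carrying the alternate, one-decimal report."""
    if tally.total_pairs == 0:
        raise ValueError("fractional abundance undefined at zero total pairs")
    return round_half_up(100.0 * tally.alt_pairs / tally.total_pairs, 1)


# ----------------------------------------------------------------------
# table-level driver
# ----------------------------------------------------------------------

def pair_tallies(
    tumor_table: pd.DataFrame, normal_table: pd.DataFrame
) -> list[tuple[AlleleTally, AlleleTally]]:
    """Match tumor rows to normal coverage on (contig, pos, ref, alt).

    A locus observed in the tumor but with no normal row at all yields a
    zero-coverage normal tally, which rule iv then rejects.  A normal row for
    the same locus but a different alternate contributes its total (the
    position *is* covered) with alternate count 0.
    """
    norm_by_alt = {
        (r.contig, int(r.pos), r.ref, r.alt): (int(r.alt_distinct_pairs), int(r.total_distinct_pairs))
        for r in normal_table.itertuples()
    }
    norm_depth: dict[tuple[str, int, str], int] = {}
    for r in normal_table.itertuples():
        norm_depth[(r.contig, int(r.pos), r.ref)] = int(r.total_distinct_pairs)
    pairs = []
    for r in tumor_table.itertuples():
        key = (r.contig, int(r.pos), r.ref, r.alt)
        tumor = AlleleTally(r.contig, int(r.pos), r.ref, r.alt, "tumor",
                            int(r.alt_distinct_pairs), int(r.total_distinct_pairs))
        n_alt, n_total = norm_by_alt.get(key, (0, norm_depth.get(key[:3], 0)))
        normal = AlleleTally(r.contig, int(r.pos), r.ref, r.alt, "normal", n_alt, n_total)
        pairs.append((tumor, normal))
    return pairs


def call_table(
    tumor_table: pd.DataFrame,
    normal_table: pd.DataFrame,
    model: GeneModel | None = None,
    reference=None,
    db: GermlineDB | None = None,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    blacklist: set[tuple[str, int, str]] | None = None,
) -> list[SomaticCall]:
    """Run the full caller over tally tables for one tumor sample.

    Rows with alternate count 0 are skipped (nothing to call).  ``blacklist``
    replaces the manual visual-inspection step: listed (contig, pos, alt)
    sites are rejected with code "quality".  Consequence annotation runs only
    when a gene model and reference are supplied.
    """
    calls = []
    for tumor, normal in pair_tallies(tumor_table, normal_table):
        if tumor.alt_pairs == 0:
            continue
        call = call_somatic(tumor, normal, db=db, thresholds=thresholds)
        if call.accepted and blacklist and (call.contig, call.pos, call.alt) in blacklist:
            call = replace(call, status="rejected", reason="quality")
        if call.accepted and model is not None and reference is not None:
            call = annotate_consequence(call, model, reference)
        calls.append(call)
    return calls
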
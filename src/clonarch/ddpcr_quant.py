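"""Poisson-partition quantification of droplet digital PCR counts.

With n droplets of volume v and k positive for a channel, the mean template
occupancy is lambda = -ln(1 - k/n) copies per droplet, hence
lambda / v * 1000 copies per microliter for v in nanoliters.  The 95%
confidence interval comes from the delta method on the binomial proportion:
SE(lambda) = sqrt(k / (n (n - k))).  Mutant fractional abundance is
c_m / (c_m + c_w) with both channel errors propagated.  Detection of mutant
circulating DNA uses a minimum mutant-positive droplet count (default 3),
and the limit of detection of a dilution series is the smallest fraction
whose simulated detection rate reaches a required level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

Z95 = 1.959963984540054  # two-sided 95% normal quantile

DEFAULT_MIN_POSITIVE_DROPLETS = 3


@dataclass(frozen=True)
class DropletCount:
    """Partition counts for one ddPCR well."""

    well: str
    mutation_id: str
    droplets_total: int
    mutant_positive: int
    wildtype_positive: int
    droplet_volume_nl: float

    def __post_init__(self):
        if self.droplets_total <= 0:
            raise ValueError("droplets_total must be positive")
        for k in (self.mutant_positive, self.wildtype_positive):
            if not 0 <= k <= self.droplets_total:
                raise ValueError("positive-droplet counts must lie in [0, droplets_total]")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")


@dataclass(frozen=True)
class ConcentrationEstimate:
    copies_per_ul: float
    ci_low: float
    ci_high: float
    channel: str  # "mutant" | "wildtype"
    lam: float = 0.0        # copies per droplet
    lam_se: float = 0.0

    def __post_init__(self):
        if not self.ci_low <= self.copies_per_ul <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")
        if self.ci_low < 0:
            raise ValueError("concentrations cannot be negative")


def estimate_concentration(count: DropletCount, channel: str) -> ConcentrationEstimate:
    """Point estimate and 95% CI for one channel's template concentration."""
    k = count.mutant_positive if channel == "mutant" else count.wildtype_positive
    n = count.droplets_total
    if k > n:
        raise ValueError("positive droplets exceed total droplets")
    if k == n:
        raise ValueError(f"{channel} channel saturated (k = n): occupancy undefined")
    lam = -math.log(1.0 - k / n)
    se = math.sqrt(k / (n * (n - k))) if k else 0.0
    scale = 1000.0 / count.droplet_volume_nl  # copies/droplet -> copies/ul
    low = max(lam - Z95 * se, 0.0)
    high = lam + Z95 * se
    return ConcentrationEstimate(
        copies_per_ul=lam * scale,
        ci_low=low * scale,
        ci_high=high * scale,
        channel=channel,
        lam=lam,
        lam_se=se,
    )


def fractional_abundance(
    mut: ConcentrationEstimate, wt: ConcentrationEstimate
) -> tuple[float, float, float]:
    """Mutant fraction 100 * c_m / (c_m + c_w) in percent, with delta-method CI.

    The fraction only depends on the occupancy ratio, so it is invariant to
    the droplet volume and to scaling both channels by a constant.
    """
    lm, lw = mut.lam, wt.lam
    total = lm + lw
    if total <= 0:
        raise ValueError("fractional abundance undefined when both channels are zero")
    frac = lm / total
    # dF/dlm = lw / total^2 ; dF/dlw = -lm / total^2
    var = (lw / total**2) ** 2 * mut.lam_se**2 + (lm / total**2) ** 2 * wt.lam_se**2
    half = Z95 * math.sqrt(var)
    low = max(frac - half, 0.0) * 100.0
    high = min(frac + half, 1.0) * 100.0
    return frac * 100.0, low, high


def detect(count: DropletCount, min_positive_droplets: int = DEFAULT_MIN_POSITIVE_DROPLETS) -> bool:
    """Mutant-DNA detection call: enough mutant-positive droplets in the well."""
    return count.mutant_positive >= min_positive_droplets


def lod_series(
    config,
    fractions_pct: Sequence[float],
    replicates: int,
    detect_rate_required: float = 0.95,
    min_positive_droplets: int = DEFAULT_MIN_POSITIVE_DROPLETS,
) -> tuple[float | None, dict[float, float]]:
    """Limit of detection of a simulated serial-dilution experiment.

    For each mutant fraction (percent, sorted descending) ``replicates``
    wells are simulated from the config's seed and the detection rule
    applied.  Returns (smallest fraction whose detection rate reaches
    ``detect_rate_required``, per-fraction detection rates); the first
    element is None when no tested fraction is reliably detectable.
    """
    from .synthetic_data import simulate_droplets

    if replicates < 1:
        raise ValueError("need at least one replicate")
    if sorted(fractions_pct, reverse=True) != list(fractions_pct):
        raise ValueError("fractions must be sorted descending")
    rates: dict[float, float] = {}
    lod: float | None = None
    for frac in fractions_pct:
        hits = 0
        for rep in range(replicates):
            count = simulate_droplets(frac, config, well=rep)
            hits += detect(count, min_positive_droplets)
        rate = hits / replicates
        rates[frac] = rate
        if rate >= detect_rate_required:
            lod = frac
    return lod, rates


# ----------------------------------------------------------------------
# NGS / fluid concordance
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceRow:
    mutation_id: str
    detected_ngs: bool
    detected_plasma: bool
    detected_sputum: bool
    abundance_ngs_pct: float | None = None
    abundance_plasma_pct: float | None = None
    abundance_sputum_pct: float | None = None


def concordance(
    ngs_calls: Mapping[str, float],
    droplet_results: Mapping[str, Mapping[str, DropletCount]],
    min_positive_droplets: int = DEFAULT_MIN_POSITIVE_DROPLETS,
) -> pd.DataFrame:
    """Cross-compartment detection table (NGS vs plasma vs sputum).

    ``ngs_calls`` maps mutation id -> NGS fractional abundance (%);
    ``droplet_results`` maps compartment ("plasma"/"sputum") -> mutation id
    -> droplet counts.  Returns one row per mutation plus a totals row
    counting detected mutations per compartment.
    """
    for compartment, wells in droplet_results.items():
        if len(set(wells)) != len(wells):
            raise ValueError(f"duplicate mutation entries in {compartment}")
    rows = []
    for mut in sorted(ngs_calls):
        entry = {
            "mutation_id": mut,
            "detected_ngs": True,
            "abundance_ngs_pct": ngs_calls[mut],
        }
        for compartment in ("plasma", "sputum"):
            count = droplet_results.get(compartment, {}).get(mut)
            detected = bool(count and detect(count, min_positive_droplets))
            entry[f"detected_{compartment}"] = detected
            abundance = None
            if count is not None and detected:
                mut_est = estimate_concentration(count, "mutant")
                wt_est = estimate_concentration(count, "wildtype")
                abundance, _, _ = fractional_abundance(mut_est, wt_est)
            entry[f"abundance_{compartment}_pct"] = abundance
        rows.append(entry)
    columns = [
        "mutation_id", "detected_ngs", "detected_plasma", "detected_sputum",
        "abundance_ngs_pct", "abundance_plasma_pct", "abundance_sputum_pct",
    ]
    table = pd.DataFrame(rows, columns=columns)
    for col in columns[4:]:
        table[col] = table[col].astype(float)
    totals = {
        "mutation_id": "TOTAL",
        "detected_ngs": int(table["detected_ngs"].sum()) if len(table) else 0,
        "detected_plasma": int(table["detected_plasma"].sum()) if len(table) else 0,
        "detected_sputum": int(table["detected_sputum"].sum()) if len(table) else 0,
        "abundance_ngs_pct": float("nan"),
        "abundance_plasma_pct": float("nan"),
        "abundance_sputum_pct": float("nan"),
    }
    table.loc[len(table)] = totals
    return table
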
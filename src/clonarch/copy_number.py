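"""Per-gene copy-number calls from tumor/normal coverage ratios.

For a targeted panel, each gene's average per-base coverage is normalized by
the sample-wide mean (optionally median) gene coverage; the tumor:normal
ratio of normalized coverages classifies the gene as amplified, deleted or
neutral against configurable fold-change cutoffs (defaults 2.0 and 0.5,
i.e. log2 ratio beyond +/-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_AMP_THRESHOLD = 2.0
DEFAULT_DEL_THRESHOLD = 0.5


@dataclass
class CoverageProfile:
    sample: str
    coverage: dict[str, float]            # gene -> average per-base coverage
    normalization_constant: float = 1.0

    def __post_init__(self):
        for gene, cov in self.coverage.items():
            if cov < 0:
                raise ValueError(f"{gene}: coverage must be >= 0")

    @classmethod
    def from_table(cls, table: pd.DataFrame, sample: str | None = None) -> "CoverageProfile":
        """Build from a coverage TSV table with columns sample, gene, avg_depth."""
        if sample is not None:
            table = table[table["sample"] == sample]
        elif table["sample"].nunique() != 1:
            raise ValueError("coverage table holds multiple samples; pass sample=")
        name = table["sample"].iloc[0]
        return cls(sample=name, coverage=dict(zip(table["gene"], table["avg_depth"].astype(float))))


@dataclass(frozen=True)
class CopyNumberCall:
    gene: str
    ratio: float
    log2_ratio: float
    call: str  # "amplification" | "deletion" | "neutral"


def normalize(profile: CoverageProfile, statistic: str = "mean") -> CoverageProfile:
    """Divide each gene's coverage by the sample-wide mean (or median) gene coverage."""
    values = list(profile.coverage.values())
    if not values or all(v == 0 for v in values):
        raise ValueError(f"{profile.sample}: cannot normalize an all-zero coverage profile")
    if statistic == "mean":
        constant = sum(values) / len(values)
    elif statistic == "median":
        constant = float(pd.Series(values).median())
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    return CoverageProfile(
        sample=profile.sample,
        coverage={g: v / constant for g, v in profile.coverage.items()},
        normalization_constant=constant,
    )


def call_cna(
    tumor: CoverageProfile,
    normal: CoverageProfile,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
    statistic: str = "mean",
) -> list[CopyNumberCall]:
    """Classify every panel gene by normalized tumor/normal coverage ratio."""
    if set(tumor.coverage) != set(normal.coverage):
        diff = sorted(set(tumor.coverage) ^ set(normal.coverage))
        raise ValueError(f"tumor/normal gene sets differ: {diff}")
    t = normalize(tumor, statistic)
    n = normalize(normal, statistic)
    calls = []
    for gene in sorted(t.coverage):
        if n.coverage[gene] <= 0:
            raise ValueError(f"{gene}: normal normalized coverage must be > 0")
        ratio = t.coverage[gene] / n.coverage[gene]
        if ratio >= amp_threshold:
            label = "amplification"
        elif ratio <= del_threshold:
            label = "deletion"
        else:
            label = "neutral"
        log2 = math.log2(ratio) if ratio > 0 else float("-inf")
        calls.append(CopyNumberCall(gene=gene, ratio=ratio, log2_ratio=log2, call=label))
    return calls


def calls_to_table(calls: list[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene, c.ratio, c.log2_ratio, c.call) for c in calls],
        columns=["gene", "ratio", "log2", "class"],
    )
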
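"""Cohort-level descriptive statistics for early-lesion panels.

Covers per-lesion mutation rates, the 12-class directional base-substitution
spectrum, cross-stage gene overlap (Venn-style membership signatures) and
the precursor-to-primary fractional-abundance progression check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from ._util import round_half_up
from .somatic_calling import SomaticCall

logger = logging.getLogger(__name__)


class StageLabel(str, Enum):
    AAH = "AAH"
    AIS = "AIS"
    MIA = "MIA"
    PRIMARY = "PRIMARY"


#: The 12 directional substitution classes; G>A and C>T are distinct on purpose
#: (spectra are reported by reference strand, not collapsed to pyrimidine context).
SUBSTITUTION_CLASSES = tuple(
    f"{ref}>{alt}" for ref in "ACGT" for alt in "ACGT" if ref != alt
)


@dataclass
class SubstitutionSpectrum:
    counts: dict[str, int]
    total_snvs: int
    excluded_indels: int = 0

    def __post_init__(self):
        if sum(self.counts.values()) != self.total_snvs:
            raise ValueError("class counts must sum to the SNV total")

    def argmax(self) -> str:
        return max(SUBSTITUTION_CLASSES, key=lambda c: self.counts.get(c, 0))


def mutation_rate(calls_per_lesion: Mapping[str, Iterable[SomaticCall]]) -> tuple[float, int, int]:
    """Mean accepted (non-synonymous) mutations per lesion, plus the range.

    The mean is reported to one decimal; lesions with zero calls count.
    """
    if not calls_per_lesion:
        raise ValueError("need at least one lesion")
    counts = [sum(1 for c in calls if c.accepted) for calls in calls_per_lesion.values()]
    mean = round_half_up(sum(counts) / len(counts), 1)
    return mean, min(counts), max(counts)


def substitution_spectrum(calls: Iterable[SomaticCall]) -> SubstitutionSpectrum:
    """Bin SNVs by directional reference>alternate class.

    Silent calls are excluded; indels are ignored with a logged count;
    records with non-ACGT alleles are skipped with a warning.
    """
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    total = indels = 0
    for call in calls:
        if call.consequence == "silent":
            continue
        if len(call.ref) != 1 or len(call.alt) != 1 or call.alt == "-":
            indels += 1
            continue
        key = f"{call.ref}>{call.alt}"
        if key not in counts:
            logger.warning("skipping SNV with non-ACGT allele at %s:%d (%s>%s)",
                           call.contig, call.pos, call.ref, call.alt)
            continue
        counts[key] += 1
        total += 1
    if indels:
        logger.info("substitution spectrum: ignored %d indels", indels)
    return SubstitutionSpectrum(counts=counts, total_snvs=total, excluded_indels=indels)


def stage_overlap(stage_gene_sets: Mapping[StageLabel | str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Partition genes by their exact stage-membership signature.

    Returns a mapping from the sorted tuple of stages a gene appears in to
    the genes with exactly that signature; the key covering *all* stages is
    always present (possibly empty) so the fully shared cell is explicit.
    """
    if len(stage_gene_sets) < 2:
        raise ValueError("need at least two stages")
    stages = [str(getattr(s, "value", s)) for s in stage_gene_sets]
    sets = {str(getattr(s, "value", s)): set(g) for s, g in stage_gene_sets.items()}
    partition: dict[tuple[str, ...], set[str]] = {}
    for gene in set().union(*sets.values()):
        signature = tuple(sorted(s for s in stages if gene in sets[s]))
        partition.setdefault(signature, set()).add(gene)
    partition.setdefault(tuple(sorted(stages)), set())
    return partition


@dataclass
class ProgressionRow:
    """One mutation tracked from precursor lesions to the primary tumour."""

    mutation: str
    samples: list[tuple[str, float]]  # (sample label, fractional abundance %), PRIMARY last

    def __post_init__(self):
        if len(self.samples) < 2:
            raise ValueError(f"{self.mutation}: need at least two samples per row")
        for label, pct in self.samples:
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{self.mutation} @ {label}: abundance {pct} outside [0, 100]")

    @property
    def increasing(self) -> bool:
        """True iff the primary strictly exceeds every earlier abundance and
        the earlier abundances are non-decreasing in listed order."""
        *earlier, (_, primary) = self.samples
        values = [pct for _, pct in earlier]
        non_decreasing = all(a <= b for a, b in zip(values, values[1:]))
        return non_decreasing and all(primary > v for v in values)


def abundance_progression(rows: Iterable[ProgressionRow]) -> tuple[list[bool], int]:
    flags = [row.increasing for row in rows]
    return flags, sum(flags)
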
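"""File dialects: tally / droplet / coverage / matrix TSVs, VCF and JSON.

All tabular formats are tab-separated UTF-8 with a header row.  Somatic
calls are written as VCF v4.2 (accepted records, with fractional abundance,
gene and consequence in INFO) plus a parallel rejected-records TSV carrying
the rule codes.  Germline exclusion lists load from VCF (via cyvcf2) or a
4-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .ddpcr_quant import DropletCount
from .somatic_calling import GermlineDB, SomaticCall
from .synthetic_data import TALLY_COLUMNS, GroundTruth

DROPLET_COLUMNS = [
    "well", "mutation_id", "droplets_total",
    "mutant_positive", "wildtype_positive", "droplet_volume_nl",
]


# ----------------------------------------------------------------------
# TSV dialects
# ----------------------------------------------------------------------

def read_tally_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str, "sample": str})
    missing = [c for c in TALLY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: tally TSV missing columns {missing}")
    return table


def write_tally_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_droplet_tsv(path: str | Path) -> list[DropletCount]:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in DROPLET_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: droplet TSV missing columns {missing}")
    return [
        DropletCount(
            well=str(r.well),
            mutation_id=str(r.mutation_id),
            droplets_total=int(r.droplets_total),
            mutant_positive=int(r.mutant_positive),
            wildtype_positive=int(r.wildtype_positive),
            droplet_volume_nl=float(r.droplet_volume_nl),
        )
        for r in table.itertuples()
    ]


def write_droplet_tsv(counts: Iterable[DropletCount], path: str | Path) -> None:
    rows = [
        (c.well, c.mutation_id, c.droplets_total, c.mutant_positive,
         c.wildtype_positive, c.droplet_volume_nl)
        for c in counts
    ]
    pd.DataFrame(rows, columns=DROPLET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path):
    from .clonal_ordering import MutationZoneMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return MutationZoneMatrix.from_frame(frame.astype(bool), lesion=Path(path).stem)


def write_matrix_tsv(matrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("sample", "gene", "avg_depth"):
        if col not in table.columns:
            raise ValueError(f"{path}: coverage TSV missing column {col}")
    return table


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=clonarch
##INFO=<ID=FA,Number=1,Type=Float,Description="Fractional abundance of the alternate allele, percent of distinct read pairs">
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted coding consequence">
"""


def write_calls_vcf(
    calls: Iterable[SomaticCall],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    rejected_path: str | Path | None = None,
) -> None:
    """Write accepted calls as VCF v4.2; optionally rejected ones as a TSV.

    Deletions written with '-' as tally alternate are emitted right-padded
    VCF-style is not needed here because the callers in this package emit
    explicit ref/alt strings; '-' alternates are encoded as symbolic <DEL>.
    """
    calls = list(calls)
    accepted = sorted((c for c in calls if c.accepted), key=lambda c: (c.contig, c.pos, c.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig, length in sorted((contig_lengths or {}).items()):
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in accepted:
            alt = "<DEL>" if c.alt == "-" else c.alt
            info = f"FA={c.fractional_abundance:.4f}"
            if c.gene:
                info += f";GENE={c.gene}"
            if c.consequence:
                info += f";CSQ={c.consequence}"
            fh.write(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{alt}\t.\tPASS\t{info}\n")
    if rejected_path is not None:
        rejected = [c for c in calls if not c.accepted]
        pd.DataFrame(
            [(c.contig, c.pos, c.ref, c.alt, c.fractional_abundance, c.reason) for c in rejected],
            columns=["contig", "pos", "ref", "alt", "fa_pct", "rule"],
        ).to_csv(rejected_path, sep="\t", index=False)


def read_germline(path: str | Path) -> GermlineDB:
    """Load a germline exclusion list from VCF (any extension cyvcf2 accepts)
    or a tab-separated file with columns contig, pos, ref, alt."""
    path = Path(path)
    db = GermlineDB()
    if path.suffix in (".vcf", ".gz", ".bcf"):
        from cyvcf2 import VCF

        for variant in VCF(str(path)):
            for alt in variant.ALT:
                db.add(variant.CHROM, variant.POS, alt)
        return db
    table = pd.read_csv(path, sep="\t")
    for r in table.itertuples():
        db.add(str(r.contig), int(r.pos), str(r.alt))
    return db


# ----------------------------------------------------------------------
# ground truth / reference
# ----------------------------------------------------------------------

def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "sites": {
            m: {"gene": s.gene, "contig": s.contig, "pos": s.pos,
                "ref": s.ref, "alt": s.alt, "consequence": s.consequence}
            for m, s in truth.sites.items()
        },
        "presence": {m: sorted(z) for m, z in truth.presence.items()},
        "cell_fraction": truth.cell_fraction,
        "fluid_fraction_pct": truth.fluid_fraction_pct,
        "germline_sites": [
            {"gene": s.gene, "contig": s.contig, "pos": s.pos, "ref": s.ref, "alt": s.alt}
            for s in truth.germline_sites
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_reference_fasta(reference: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in sorted(reference):
            fh.write(f">{contig}\n")
            seq = reference[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
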
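"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 (GT only, unphased, ``./.`` for missing);
plot data and era labels as plain CSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, InputError, validate_plot_table

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> str:
    """Write a GT-only VCF v4.2 with one sample column per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=maizegca\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(genotypes.variants["chrom"]), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.line_ids) + "\n")
        for j, row in enumerate(genotypes.variants.itertuples(index=False)):
            calls = [
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")
    return str(path)


def load_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Load a VCF into a dosage matrix; multi-allelic records are kept but
    flagged (``n_alleles`` > 2) so QC can drop them."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise InputError(f"cannot parse VCF {path}: {exc}") from exc
    line_ids = list(vcf.samples)
    rows, dosage_rows = [], []
    for rec in vcf:
        n_alt = len(rec.ALT)
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(cyvcf2: 3), 2/3 handling below
        types = rec.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        d = np.full(len(line_ids), np.nan)
        d[types == 0] = 0.0
        d[types == 1] = 1.0
        d[types == 3] = 2.0
        dosage_rows.append(d)
        rows.append(
            {
                "snp_id": rec.ID if rec.ID not in (None, ".") else f"S{rec.CHROM}_{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": ",".join(rec.ALT),
                "n_alleles": 1 + n_alt,
                "causal_trait": "",
            }
        )
    vcf.close()
    if not rows:
        raise InputError(f"VCF {path} contains no variant records")
    variants = pd.DataFrame(rows)
    # normalize chrom dtype to int where possible (matches the simulator)
    try:
        variants["chrom"] = variants["chrom"].astype(int)
    except (TypeError, ValueError):
        pass
    return GenotypeMatrix(np.column_stack(dosage_rows), line_ids, variants)


def write_plot_table(plots: pd.DataFrame, path: str | os.PathLike) -> str:
    validate_plot_table(plots)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plots.to_csv(path, index=False)
    return str(path)


def read_plot_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"plot table not found: {path}")
    plots = pd.read_csv(path, dtype={"line_id": str, "tester_id": str,
                                     "location": str, "block": str})
    validate_plot_table(plots)
    return plots


def write_eras(eras: pd.Series, path: str | os.PathLike) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    eras.rename("era").rename_axis("line_id").reset_index().to_csv(path, index=False)
    return str(path)


def read_eras(path: str | os.PathLike) -> pd.Series:
    path = Path(path)
    if not path.exists():
        raise InputError(f"era table not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if not {"line_id", "era"}.issubset(df.columns):
        raise InputError("era CSV needs columns line_id, era")
    bad = set(df["era"]) - {"AGE1", "AGE2", "AGE3"}
    if bad:
        raise InputError(f"unknown era labels: {sorted(bad)}")
    if df["line_id"].duplicated().any():
        raise InputError("duplicate line_id in era CSV")
    return pd.Series(df["era"].to_numpy(), index=df["line_id"], name="era")


def write_fixtures(
    genotypes: GenotypeMatrix,
    eras: pd.Series,
    plots: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write VCF + plots CSV + era CSV that round-trip through the readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "vcf": write_vcf(genotypes, out / "genotypes.vcf"),
        "plots": write_plot_table(plots, out / "plots.csv"),
        "eras": write_eras(eras, out / "eras.csv"),
    }
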
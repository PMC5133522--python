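"""Reading and writing genotype/phenotype data and result tables.

Genotypes travel either as VCF 4.x with a per-sample DS (dosage) FORMAT
field — read via pysam; when DS is absent the GT allele sum is used —
or as a plain TSV matrix (first column sample id, remaining columns one
variant each).  Dosages are written with 3-decimal precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .containers import GenotypeMatrix, PhenotypeTable, VariantInfo

__all__ = [
    "read_genotypes",
    "read_genotypes_vcf",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "write_results_tsv",
    "write_manifest",
]

_PHENO_COLS = ("outcome", "sbp", "dbp", "meds", "age", "sex", "q1")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf/.vcf.gz -> VCF reader, else TSV."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_genotypes_vcf(p)
    return read_genotypes_tsv(p)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Per-sample dosage from the DS FORMAT field, else the GT allele sum."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    cols = []
    variants = []
    for rec in vf:
        has_ds = "DS" in rec.format
        col = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            if has_ds and call.get("DS") is not None:
                col[i] = float(call["DS"])
            else:
                gt = call.get("GT")
                if gt is not None and not all(a is None for a in gt):
                    col[i] = float(sum(a for a in gt if a is not None))
        cols.append(col)
        vid = rec.id if rec.id not in (None, ".") else f"var_{rec.chrom}_{rec.pos}"
        variants.append(VariantInfo(id=vid, chrom=str(rec.chrom), pos=int(rec.pos)))
    vf.close()
    dos = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    gm = GenotypeMatrix(dos, samples, variants)
    gm.annotate()
    return gm


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with a DS FORMAT field (3-decimal dosages)."""
    chroms = sorted({v.chrom for v in gm.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        order = np.lexsort((gm.positions, [v.chrom for v in gm.variants]))
        for j in order:
            v = gm.variants[j]
            vals = [
                "." if np.isnan(d) else f"{d:.3f}" for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\tA\tC\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n"
            )


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """TSV matrix: header of variant ids, first column the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    variants = [VariantInfo(id=str(c)) for c in df.columns]
    gm = GenotypeMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index], variants)
    gm.annotate()
    return gm


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.round(gm.dosages, 3),
        index=pd.Index(gm.sample_ids, name="sample_id"),
        columns=[v.id for v in gm.variants],
    )
    df.to_csv(path, sep="\t")


def read_phenotypes_tsv(path: str | Path) -> PhenotypeTable:
    """Phenotype TSV: sample_id plus any of outcome/sbp/dbp/meds/age/sex/q1."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype file must have a sample_id column")
    n = len(df)
    kw = {}
    for col in _PHENO_COLS:
        if col in df.columns:
            kw[col] = df[col].to_numpy(dtype=float)
    for required in ("outcome", "age", "sex"):
        kw.setdefault(required, np.full(n, np.nan))
    return PhenotypeTable(sample_ids=[str(s) for s in df["sample_id"]], **kw)


def write_phenotypes_tsv(pt: PhenotypeTable, path: str | Path) -> None:
    pt.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_results_tsv(results, path: str | Path) -> None:
    """TestResult list to a tidy TSV."""
    rows = []
    for r in results:
        row = {
            "target": r.target,
            "method": r.method,
            "statistic": r.statistic,
            "p": r.p_value,
            "status": r.status.value,
        }
        for key in ("class", "m", "path", "df"):
            if key in r.df_or_params:
                row[key] = r.df_or_params[key]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (seeds, spec hash, version, counters)."""
    from . import __version__

    payload = {"sparseassoc_version": __version__, **entries}

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
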
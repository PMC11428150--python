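"""Reading and writing genotype matrices and layer tables.

Three genotype dialects are supported: a plain samples x SNPs TSV, VCF
(alternate-allele counts from the GT field, 1-based coordinates per the VCF
standard) and the plink ``.raw`` additive-coding export.  SNP identity is
the rsID-style label throughout; positions are not used internally.
Missing genotypes become NaN.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, ParseError

__all__ = ["read_genotypes", "write_genotypes_tsv", "write_genotypes_vcf"]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Load an additive 0/1/2 genotype matrix with sample and SNP labels."""
    path = Path(path)
    if not path.exists():
        raise InvalidArgumentError(f"no such file: {path}")
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    raise InvalidArgumentError(f"unknown genotype format {format!r}")


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse TSV {path}: {exc}") from exc
    df.index.name = "sample"
    bad = ~(df.isna() | df.isin([0, 1, 2]))
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise ParseError(f"non-additive genotype value in {path}", line=row + 2)
    return df.astype(float)


def _gt_to_dose(gt: str) -> float:
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles or gt in (".", ""):
        return np.nan
    try:
        return float(sum(int(a) > 0 for a in alleles))
    except ValueError:
        return np.nan


def _read_vcf(path: Path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None:
        try:
            vcf = VCF(str(path))
            samples = list(vcf.samples)
            labels, rows = [], []
            for var in vcf:
                labels.append(var.ID or f"{var.CHROM}:{var.POS}")
                # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
                doses = np.array(
                    [{0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}[t] for t in var.gt_types]
                )
                rows.append(doses)
            mat = np.array(rows).T if rows else np.empty((len(samples), 0))
            df = pd.DataFrame(mat, index=pd.Index(samples, name="sample"), columns=labels)
            return df
        except Exception:
            pass  # fall through to the text parser
    return _read_vcf_text(path)


def _read_vcf_text(path: Path) -> pd.DataFrame:
    samples: list[str] = []
    labels, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ParseError("VCF has no sample columns", line=lineno)
                samples = fields[9:]
                continue
            if not samples:
                raise ParseError("VCF data before #CHROM header", line=lineno)
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ParseError("wrong number of VCF columns", line=lineno)
            chrom, pos, vid = fields[0], fields[1], fields[2]
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ParseError("record without GT field", line=lineno)
            gt_i = fmt.index("GT")
            labels.append(vid if vid not in (".", "") else f"{chrom}:{pos}")
            rows.append([_gt_to_dose(s.split(":")[gt_i]) for s in fields[9:]])
    if not samples:
        raise ParseError("no #CHROM header found in VCF")
    mat = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return pd.DataFrame(mat, index=pd.Index(samples, name="sample"), columns=labels)


def _read_plink_raw(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise ParseError(f"cannot parse plink .raw {path}: {exc}") from exc
    missing_meta = [c for c in _PLINK_META if c not in df.columns]
    if missing_meta:
        raise ParseError(f"plink .raw missing columns {missing_meta}", line=1)
    geno = df.drop(columns=_PLINK_META)
    # plink suffixes each SNP with the counted allele, e.g. rs123_A
    geno.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    geno.index = pd.Index(df["IID"].astype(str), name="sample")
    return geno.astype(float)


def write_genotypes_tsv(genotypes: pd.DataFrame, path: str | Path) -> None:
    out = genotypes.copy()
    # keep integer formatting where nothing is missing
    if not out.isna().to_numpy().any():
        out = out.astype(int)
    out.to_csv(path, sep="\t", index_label="sample")


def write_genotypes_vcf(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Minimal single-chromosome VCF export (synthetic coordinates)."""
    dose_to_gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.index.astype(str))
            + "\n"
        )
        for j, snp in enumerate(genotypes.columns):
            gts = []
            for v in genotypes[snp]:
                gts.append("./." if pd.isna(v) else dose_to_gt[int(v)])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
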
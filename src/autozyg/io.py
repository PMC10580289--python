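"""File formats: site-major genotype tables, VCF v4.2, segment TSVs.

The native genotype format is a site-major TSV with columns
``chrom  pos_bp  pos_cm  <sample1>  <sample2> ...`` where genotype cells
are alternate-allele counts in {0,1,2} or ``NA``.  VCF interchange is
restricted to biallelic SNVs with GT-only FORMAT; missing calls are
``./.``.  Round trips between the two formats are lossless for calls and
site coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import StructuralError

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_vcf",
    "read_vcf",
    "write_segments_tsv",
    "read_phenotypes_tsv",
]

MISSING = -1


def write_genotypes_tsv(path, genotypes: np.ndarray, sites: pd.DataFrame,
                        sample_ids: list[str]) -> None:
    """Write (n_samples, n_sites) genotypes site-major; missing (<0) -> NA."""
    G = np.asarray(genotypes)
    if G.shape != (len(sample_ids), len(sites)):
        raise StructuralError("genotype matrix does not match samples x sites")
    out = sites[["chrom", "pos_bp", "pos_cm"]].copy()
    for i, s in enumerate(sample_ids):
        col = G[i].astype(object)
        col[G[i] < 0] = "NA"
        out[s] = col
    out.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "pos_bp", "pos_cm"]
    if df.columns[:3].tolist() != meta:
        raise StructuralError(f"expected leading columns {meta}")
    sample_ids = df.columns[3:].tolist()
    G = (
        df[sample_ids]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(MISSING)
        .to_numpy()
        .astype(np.int8)
        .T
    )
    return G, df[meta].copy(), sample_ids


def write_vcf(path, genotypes: np.ndarray, sites: pd.DataFrame,
              sample_ids: list[str]) -> None:
    """Write biallelic GT-only VCF v4.2 (unphased; REF=A, ALT=G placeholder
    alleles for array-style 0/1/2 calls)."""
    G = np.asarray(genotypes)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos_bp'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        pos = sites["pos_bp"].to_numpy()
        chroms = sites["chrom"].to_numpy()
        for j in range(len(sites)):
            calls = "\t".join(gt_map[int(g)] for g in G[:, j])
            fh.write(f"{chroms[j]}\t{int(pos[j])}\t.\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a biallelic GT-only VCF via cyvcf2; multi-allelic records are
    rejected with their position."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, genos = [], []
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise StructuralError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(record {k + 1}); only biallelic SNVs are supported"
            )
        gt = np.asarray(var.genotype.array())[:, :2]
        calls = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        genos.append(calls.astype(np.int8))
        rows.append({"chrom": var.CHROM, "pos_bp": var.POS})
    sites = pd.DataFrame(rows)
    sites["pos_cm"] = np.nan
    G = np.column_stack(genos) if genos else np.empty((len(sample_ids), 0), np.int8)
    return G, sites, sample_ids


def write_segments_tsv(path, segments: pd.DataFrame) -> None:
    """Segment table mirroring PLINK .hom columns plus genetic length."""
    out = pd.DataFrame(
        {
            "FID": segments["sample_id"],
            "IID": segments["sample_id"],
            "CHR": segments["chrom"],
            "POS1": segments["start_bp"],
            "POS2": segments["end_bp"],
            "KB": segments["length_kb"],
            "NSNP": segments["n_snps"],
            "CM": segments.get("length_cm", np.nan),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise StructuralError("phenotype table needs a sample_id column")
    return df


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
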
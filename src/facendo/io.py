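"""Plain-text interchange formats.

Landmarks travel as long-format TSV (id, landmark_index, x, y, z); covariates,
QC reports, summary statistics, score tables and hierarchies as TSV; segment
models as JSON sidecars; genotypes as uncompressed VCF (GT fields, REF=major,
ALT=minor) or PLINK-style transposed text (.traw-like).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas import GenotypeTable
from .segmentation import Segment, SegmentHierarchy, SegmentModel

__all__ = [
    "write_landmarks_tsv",
    "read_landmarks_tsv",
    "write_vcf",
    "read_vcf",
    "write_plink_traw",
    "read_plink_traw",
    "write_hierarchy_tsv",
    "read_hierarchy_tsv",
    "write_segment_models",
    "read_segment_models",
]


def write_landmarks_tsv(path, configs: np.ndarray, ids=None) -> None:
    configs = np.asarray(configs, dtype=float)
    n, p, _ = configs.shape
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(n)]
    rows = {
        "id": np.repeat(ids, p),
        "landmark_index": np.tile(np.arange(p), n),
        "x": configs[:, :, 0].ravel(),
        "y": configs[:, :, 1].ravel(),
        "z": configs[:, :, 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_landmarks_tsv(path):
    df = pd.read_csv(path, sep="\t")
    ids = list(dict.fromkeys(df["id"]))
    p = df["landmark_index"].max() + 1
    configs = np.empty((len(ids), p, 3))
    for i, ind in enumerate(ids):
        sub = df[df["id"] == ind].sort_values("landmark_index")
        configs[i] = sub[["x", "y", "z"]].to_numpy()
    return configs, ids


def write_vcf(path, table: GenotypeTable) -> None:
    """Uncompressed VCF with hard GT calls; REF = major allele, ALT = minor."""
    meta = table.snp_meta
    n = table.n
    ids = table.ids or [f"ind{i + 1}" for i in range(n)]
    sex = table.sex if table.sex is not None else np.zeros(n, dtype=int)
    minor_counts = (2.0 - table.dosages).round().astype(int)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(meta["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, ids)) + "\n")
        for j in range(table.n_snps):
            row = meta.iloc[j]
            is_x = str(row["chrom"]).upper() == "X"
            gts = []
            for i in range(n):
                c = minor_counts[i, j]
                if is_x and sex[i] == 1:
                    gts.append("1" if c > 0 else "0")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(c)])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t{row['allele_major']}\t"
                f"{row['allele_minor']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, sex: np.ndarray | None = None) -> GenotypeTable:
    """Read a biallelic VCF into a major-allele-coded GenotypeTable.

    Parsing goes through cyvcf2.  The REF allele is taken as major (as
    written by :func:`write_vcf`); hemizygous male X calls (haploid GT, or
    homozygous diploid for a male) become dosages in {0, 2}.  Multi-allelic
    sites are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    sex = np.zeros(n, dtype=int) if sex is None else np.asarray(sex, dtype=int)
    cols, meta_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic site {var.ID} not supported")
        is_x = str(var.CHROM).upper() in {"X", "CHRX"}
        dos = np.empty(n)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                dos[i] = np.nan
            elif len(alleles) == 1:  # haploid call
                dos[i] = 0.0 if alleles[0] else 2.0
            elif is_x and sex[i] == 1:
                if alleles[0] != alleles[1]:
                    raise ValueError(f"heterozygous male X call at {var.ID}")
                dos[i] = 0.0 if alleles[0] else 2.0
            else:
                dos[i] = 2.0 - sum(alleles)
        cols.append(dos)
        valid = dos[np.isfinite(dos)]
        maf = float(np.sum(2.0 - valid) / (2.0 * valid.size)) if valid.size else 0.0
        meta_rows.append(
            {
                "snp": var.ID,
                "chrom": str(var.CHROM),
                "pos": var.POS,
                "allele_major": var.REF,
                "allele_minor": var.ALT[0],
                "maf": min(maf, 1.0 - maf),
            }
        )
    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    return GenotypeTable(dosages=dosages, snp_meta=pd.DataFrame(meta_rows), sex=sex, ids=samples)


def write_plink_traw(path, table: GenotypeTable) -> None:
    """PLINK-style transposed dosage text: one row per SNP, one column per sample."""
    ids = table.ids or [f"ind{i + 1}" for i in range(table.n)]
    meta = table.snp_meta
    df = pd.DataFrame(
        {
            "CHR": meta["chrom"],
            "SNP": meta["snp"],
            "CM": 0,
            "POS": meta["pos"],
            "COUNTED": meta["allele_major"],
            "ALT": meta["allele_minor"],
        }
    )
    dos = pd.DataFrame(table.dosages.T, columns=ids)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_plink_traw(path, sex: np.ndarray | None = None) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t")
    fixed = ["CHR", "SNP", "CM", "POS", "COUNTED", "ALT"]
    samples = [c for c in df.columns if c not in fixed]
    dosages = df[samples].to_numpy(dtype=float).T
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    meta = pd.DataFrame(
        {
            "snp": df["SNP"],
            "chrom": df["CHR"].astype(str),
            "pos": df["POS"],
            "allele_major": df["COUNTED"],
            "allele_minor": df["ALT"],
            "maf": np.minimum(freq, 1.0 - freq),
        }
    )
    return GenotypeTable(dosages=dosages, snp_meta=meta, sex=sex, ids=samples)


def write_hierarchy_tsv(path, hierarchy: SegmentHierarchy) -> None:
    rows = [
        {
            "segment_id": s.segment_id,
            "level": s.level,
            "parent_id": -1 if s.parent_id is None else s.parent_id,
            "landmarks": ",".join(map(str, s.landmarks)),
        }
        for s in hierarchy.segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hierarchy_tsv(path) -> SegmentHierarchy:
    df = pd.read_csv(path, sep="\t")
    segs = [
        Segment(
            segment_id=int(r["segment_id"]),
            level=int(r["level"]),
            landmarks=np.array([int(v) for v in str(r["landmarks"]).split(",")]),
            parent_id=None if int(r["parent_id"]) == -1 else int(r["parent_id"]),
        )
        for _, r in df.iterrows()
    ]
    return SegmentHierarchy(segments=segs)


def write_segment_models(path, models: dict) -> None:
    payload = {
        str(sid): {
            "segment_id": m.segment_id,
            "landmarks": m.landmarks.tolist(),
            "mean_shape": m.mean_shape.tolist(),
            "basis": m.basis.tolist(),
            "eigenvalues": m.eigenvalues.tolist(),
        }
        for sid, m in models.items()
    }
    Path(path).write_text(json.dumps(payload))


def read_segment_models(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        int(sid): SegmentModel(
            segment_id=d["segment_id"],
            landmarks=np.array(d["landmarks"], dtype=int),
            mean_shape=np.array(d["mean_shape"]),
            basis=np.array(d["basis"]),
            eigenvalues=np.array(d["eigenvalues"]),
        )
        for sid, d in payload.items()
    }
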
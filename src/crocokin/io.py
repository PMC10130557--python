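"""Readers and writers for the formats the pipeline exchanges.

Genotypes travel as GT-only VCF (chromosome "1", 1-based positions,
synthetic A/T alleles for simulated data) or as CSV (individuals x sites);
pedigrees and truth tables as TSV; read counts as the two-row CSV layout
(one row per locus x allele, columns are individuals); coastlines as an
ordered lon/lat CSV or a GeoJSON LineString.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dartqc import ReadCountMatrix
from .simulate import SampleSet

__all__ = ["write_vcf", "read_vcf", "write_genotypes_csv", "read_genotypes_csv",
           "write_pedigree", "read_pedigree", "write_readcounts_csv",
           "read_readcounts_csv", "read_coastline"]


def write_vcf(sample: SampleSet, path) -> None:
    """Write a SampleSet as a minimal GT-only VCF (sorted by position)."""
    order = np.argsort(sample.positions, kind="stable")
    geno = sample.genotypes[:, order]
    pos = sample.positions[order]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        names = "\t".join(str(i) for i in sample.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for j in range(pos.size):
            gts = "\t".join(gt_map[int(g)] for g in geno[:, j])
            fh.write(f"1\t{int(pos[j]) + 1}\tsite{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a GT-only VCF into (genotypes, sample names, positions).

    Uses cyvcf2 when importable, otherwise a plain-text parse; genotypes
    are alt-allele dosage with NaN for missing.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, pos = [], []
        for var in vcf:
            gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 dosage; 2=unknown
            gt[gt == 2] = np.nan
            gt[gt == 3] = 2.0
            rows.append(gt)
            pos.append(var.POS)
        G = np.array(rows).T if rows else np.empty((len(samples), 0))
        return G, samples, np.asarray(pos, dtype=np.int64)
    samples, rows, pos = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            pos.append(int(parts[1]))
            g = []
            for entry in parts[9:]:
                gt = entry.split(":")[0].replace("|", "/")
                if "." in gt:
                    g.append(np.nan)
                else:
                    g.append(sum(int(a) for a in gt.split("/")))
            rows.append(g)
    G = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return G, samples, np.asarray(pos, dtype=np.int64)


def write_genotypes_csv(G, ids, path, positions=None) -> None:
    cols = ([f"pos{p}" for p in positions] if positions is not None
            else [f"site{j}" for j in range(np.asarray(G).shape[1])])
    pd.DataFrame(np.asarray(G), index=pd.Index(ids, name="id"),
                 columns=cols).to_csv(path)


def read_genotypes_csv(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy(), list(df.columns)


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_readcounts_csv(counts: ReadCountMatrix, path) -> None:
    """Two-row layout: rows are locus x allele, columns are individuals."""
    n = counts.n_loci
    rows = []
    for i in range(n):
        rows.append([counts.locus_ids[i], "ref",
                     counts.fragments[i] if counts.fragments is not None else ""]
                    + list(counts.ref[i]))
        rows.append([counts.locus_ids[i], "alt",
                     counts.fragments[i] if counts.fragments is not None else ""]
                    + list(counts.alt[i]))
    cols = ["locus", "allele", "fragment"] + list(map(str, counts.individual_ids))
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_readcounts_csv(path, pops=None) -> ReadCountMatrix:
    df = pd.read_csv(path)
    ind_cols = [c for c in df.columns if c not in ("locus", "allele", "fragment")]
    ref = df[df["allele"] == "ref"]
    alt = df[df["allele"] == "alt"]
    ref = ref.set_index("locus")
    alt = alt.set_index("locus").loc[ref.index]
    frag = ref["fragment"].to_numpy() if "fragment" in ref else None
    return ReadCountMatrix(
        ref=ref[ind_cols].to_numpy(dtype=np.int64),
        alt=alt[ind_cols].to_numpy(dtype=np.int64),
        locus_ids=ref.index.to_numpy(),
        individual_ids=np.asarray(ind_cols),
        fragments=frag, pops=pops)


def read_coastline(path) -> np.ndarray:
    """Ordered (n, 2) lon/lat polyline from CSV (lon,lat columns) or
    GeoJSON LineString."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        obj = json.loads(path.read_text())
        if "features" in obj:
            obj = obj["features"][0]["geometry"]
        if "geometry" in obj:
            obj = obj["geometry"]
        return np.asarray(obj["coordinates"], dtype=float)
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    return df[[cols["lon"], cols["lat"]]].to_numpy(dtype=float)
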
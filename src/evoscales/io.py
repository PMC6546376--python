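"""File formats: phenotype TSV, VCF, plain haplotype matrices, population
maps and BED-like track TSVs.

Conventions: all in-memory coordinates are 0-based; VCF is 1-based and the
conversion happens only here.  Track files are 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen_stats import GenotypeMatrix, HaplotypeMatrix, ScanTrack

PHENO_COLUMNS = ["id", "year", "bill_mm", "tarsus_mm", "sex", "site"]

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_vcf",
    "write_vcf",
    "read_haplotype_text",
    "write_haplotype_text",
    "read_pop_map",
    "write_pop_map",
    "write_track",
]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("id", "year", "bill_mm") if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table is missing columns: {missing}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    cols = [c for c in PHENO_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def write_pop_map(labels, samples, path) -> None:
    pd.DataFrame({"sample": samples, "population": labels}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_pop_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    data: GenotypeMatrix | HaplotypeMatrix,
    path,
    sample_names=None,
    phased: bool | None = None,
) -> None:
    """Write a single-chromosome biallelic VCF (GT only).

    Haplotype matrices are written phased (``0|1``); genotype matrices
    unphased (``0/1``, ``./.`` for missing).  Positions are converted to
    VCF's 1-based coordinates.
    """
    if isinstance(data, HaplotypeMatrix):
        if data.n_hap % 2:
            raise ValueError("phased VCF output needs an even haplotype count")
        n_samp = data.n_hap // 2
        phased = True if phased is None else phased
    else:
        n_samp = data.n_ind
        phased = False if phased is None else phased
    if sample_names is None:
        sample_names = [f"s{i}" for i in range(n_samp)]
    sep = "|" if phased else "/"
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={data.chrom},length={_contig_length(data)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        if isinstance(data, HaplotypeMatrix):
            for j in range(data.n_sites):
                col = data.alleles[:, j]
                gt_field = "\t".join(
                    f"{col[2 * i]}{sep}{col[2 * i + 1]}" for i in range(n_samp)
                )
                fh.write(
                    f"{data.chrom}\t{data.positions[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gt_field}\n"
                )
        else:
            code = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", -1: "./."}
            for j in range(data.n_sites):
                gt_field = "\t".join(code[int(d)] for d in data.dosages[:, j])
                fh.write(
                    f"{data.chrom}\t{data.positions[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gt_field}\n"
                )


def _contig_length(data) -> int:
    if isinstance(data, HaplotypeMatrix):
        return int(data.length)
    return int(data.positions[-1]) + 1 if data.positions.size else 1


def read_vcf(path, region: str | None = None, pop_map=None, skip_multiallelic=True):
    """Read a single-chromosome VCF into a GenotypeMatrix (plus a
    HaplotypeMatrix when every genotype is phased and called).

    Positions are converted 1-based -> 0-based.  Multi-allelic records are
    skipped (default) or raise.  Returns ``(GenotypeMatrix,
    HaplotypeMatrix | None)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, dosages, haps = [], [], []
    chrom = None
    all_phased = True
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("matrix must hold a single chromosome per file")
        positions.append(var.POS - 1)
        gts = var.genotype.array()  # (n, 3): a0, a1, phased flag
        a = gts[:, 0].astype(np.int16)
        b = gts[:, 1].astype(np.int16)
        miss = (a < 0) | (b < 0)
        dos = np.where(miss, -1, a + b).astype(np.int16)
        dosages.append(dos)
        if miss.any() or not gts[:, 2].all():
            all_phased = False
        else:
            haps.append(np.column_stack([a, b]).reshape(-1).astype(np.uint8))
    vcf.close()
    if not positions:
        raise ValueError(f"no biallelic records found in {path}")
    pos = np.asarray(positions, dtype=np.int64)
    labels = None
    if pop_map is not None:
        pm = read_pop_map(pop_map) if not isinstance(pop_map, pd.DataFrame) else pop_map
        lab = pm.set_index("sample")["population"]
        labels = np.array([lab.get(s, "?") for s in samples])
    gm = GenotypeMatrix(np.column_stack(dosages), pos, chrom or "1", labels)
    hm = None
    if all_phased and len(haps) == len(positions):
        hm = HaplotypeMatrix(np.column_stack(haps), pos, chrom or "1")
    return gm, hm


# ---------------------------------------------------------------------------
# plain-text haplotype matrix
# ---------------------------------------------------------------------------


def write_haplotype_text(hm: HaplotypeMatrix, path) -> None:
    """Header lines (#chrom, #length, #positions) then one 0/1 row per
    haplotype."""
    with open(path, "wt") as fh:
        fh.write(f"#chrom\t{hm.chrom}\n#length\t{hm.length}\n")
        fh.write("#positions\t" + "\t".join(map(str, hm.positions)) + "\n")
        for row in hm.alleles:
            fh.write("".join(map(str, row)) + "\n")


def read_haplotype_text(path) -> HaplotypeMatrix:
    chrom, length, positions = "1", None, None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#chrom"):
                chrom = line.split("\t")[1]
            elif line.startswith("#length"):
                length = int(line.split("\t")[1])
            elif line.startswith("#positions"):
                positions = np.array(line.split("\t")[1:], dtype=np.int64)
            elif line:
                rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if positions is None:
        raise ValueError("missing #positions header line")
    return HaplotypeMatrix(np.vstack(rows), positions, chrom, length)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def write_track(track: ScanTrack, path) -> None:
    """BED-like TSV: chrom, start, end, statistic, raw, smoothed.

    Windowed tracks write their half-open window bounds; per-SNP tracks
    write ``[pos, pos+1)``.
    """
    if track.window is not None:
        size = track.window[0]
        starts = (track.positions - size / 2).astype(np.int64)
        ends = starts + size
    else:
        starts = track.positions.astype(np.int64)
        ends = starts + 1
    df = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": starts,
            "end": ends,
            "statistic": track.statistic,
            "raw": track.raw,
            "smoothed": track.smoothed if track.smoothed is not None else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulator configuration
# ---------------------------------------------------------------------------


def load_sim_config(path):
    """Build ForwardSimParams from a YAML or JSON config file.

    Expected keys mirror the dataclass: N, L, mu, seed, sample_n, burnin
    (optional), dfe {p_deleterious, s_mean, s_shape, h}, and either
    recomb_map {intervals: [[start, end, rate], ...]} or
    recomb_map {base_rate, coldspot: {start, length, factor}}.
    A top-level rescale_Q applies population rescaling after construction.
    """
    import yaml

    from .forward_sim import (
        DFEConfig,
        ForwardSimParams,
        RecombinationMap,
        rescale_params,
    )

    cfg = yaml.safe_load(Path(path).read_text())
    rm = cfg["recomb_map"]
    if "intervals" in rm:
        recomb = RecombinationMap.from_intervals(
            [tuple(iv) for iv in rm["intervals"]]
        )
    elif "coldspot" in rm:
        cs = rm["coldspot"]
        recomb = RecombinationMap.with_coldspot(
            cfg["L"], rm["base_rate"], cs["start"], cs["length"],
            cs.get("factor", 0.01),
        )
    else:
        recomb = RecombinationMap.uniform(cfg["L"], rm["base_rate"])
    params = ForwardSimParams(
        N=cfg["N"],
        L=cfg["L"],
        mu=cfg["mu"],
        recomb_map=recomb,
        dfe=DFEConfig(**cfg.get("dfe", {})),
        burnin=cfg.get("burnin"),
        sample_n=cfg.get("sample_n", 100),
        seed=cfg.get("seed", 0),
    )
    q = cfg.get("rescale_Q", 1)
    return rescale_params(params, q) if q != 1 else params
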
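"""Genome-scan statistics over haplotype and genotype matrices.

The suite covers the statistics used to contrast a recombination coldspot
against the rest of a chromosome: haplotype r² and its decay with distance,
a long-distance (20–200 kb) LD track, per-SNP Hudson FST, eigenGWAS with
genomic control, site extended haplotype homozygosity (EHHS) and its
integral iES, and windowed nucleotide diversity π.  All coordinates are
0-based bp; windows are half-open ``[start, start + size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._smoothing import gaussian_kernel_smooth, loess

__all__ = [
    "HaplotypeMatrix",
    "GenotypeMatrix",
    "ScanTrack",
    "EigenGWASResult",
    "EhhsCurve",
    "pairwise_r2",
    "ld_decay_curve",
    "long_distance_ld_track",
    "hudson_fst_per_snp",
    "eigengwas_scan",
    "ehhs_curve",
    "ies_scan",
    "pi_windows",
    "smooth_track",
]

# median of a 1-df chi-square, the genomic-control null median
_CHI2_1_MEDIAN = float(sps.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMatrix:
    """Phased binary alleles, one row per haplotype, one column per site.

    ``positions`` are 0-based bp, strictly increasing and unique.  ``length``
    is the chromosome length in bp; when omitted it defaults to one past the
    last site.  Haplotypes ``2i`` and ``2i+1`` are assumed to belong to
    individual ``i`` when the matrix is converted to genotypes.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    length: int | None = None

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (n_hap, n_sites) array")
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions length must match the number of sites")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing (no duplicates)")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be binary 0/1")
        if self.length is None:
            self.length = int(self.positions[-1]) + 1 if self.positions.size else 0
        if self.positions.size and self.length <= self.positions[-1]:
            raise ValueError("length must exceed the last position")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.derived_freq()
        return np.minimum(p, 1 - p)

    def filter_maf(self, min_maf: float) -> "HaplotypeMatrix":
        keep = self.maf() >= min_maf
        return HaplotypeMatrix(
            self.alleles[:, keep], self.positions[keep], self.chrom, self.length
        )

    def to_genotypes(self, pop_labels=None) -> "GenotypeMatrix":
        if self.n_hap % 2:
            raise ValueError("need an even number of haplotypes to pair into diploids")
        dos = self.alleles[0::2].astype(np.int16) + self.alleles[1::2]
        return GenotypeMatrix(dos, self.positions.copy(), self.chrom, pop_labels)


@dataclass
class GenotypeMatrix:
    """Diploid dosages (0/1/2, -1 for missing), one row per individual."""

    dosages: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    pop_labels: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int16)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (n_ind, n_sites)")
        if self.positions.shape != (self.dosages.shape[1],):
            raise ValueError("positions length must match the number of sites")
        if self.dosages.size and (self.dosages.max() > 2 or self.dosages.min() < -1):
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        if self.pop_labels is not None:
            self.pop_labels = np.asarray(self.pop_labels)
            if self.pop_labels.shape != (self.dosages.shape[0],):
                raise ValueError("pop_labels must cover all individuals")

    @property
    def n_ind(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def allele_counts(self, rows=None):
        """(derived allele count, called allele count) per site over ``rows``."""
        d = self.dosages if rows is None else self.dosages[rows]
        called = d >= 0
        ac = np.where(called, d, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        return ac, an


@dataclass
class ScanTrack:
    """Per-position raw (and optionally smoothed) values of one statistic."""

    statistic: str
    positions: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    chrom: str = "1"
    window: tuple[int, int] | None = None  # (size, step) bp when windowed
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.positions.shape != self.raw.shape:
            raise ValueError("positions and raw must have the same length")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.shape != self.raw.shape:
                raise ValueError("smoothed must be on the same grid as raw")

    def to_dataframe(self):
        import pandas as pd

        d = {"chrom": self.chrom, "position": self.positions, "raw": self.raw}
        if self.smoothed is not None:
            d["smoothed"] = self.smoothed
        return pd.DataFrame(d)

    def mean_in(self, start: float, end: float) -> float:
        """Mean raw value over positions in [start, end), ignoring NaN."""
        m = (self.positions >= start) & (self.positions < end)
        vals = self.raw[m]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")


@dataclass
class EigenGWASResult:
    positions: np.ndarray
    chi2: np.ndarray
    p_raw: np.ndarray
    p_gc: np.ndarray
    lambda_gc: float
    scores: np.ndarray        # leading eigenvector, one entry per individual
    eigenvalues: np.ndarray   # leading eigenvalues of the GRM
    kept: np.ndarray          # indices of SNPs that survived the MAF filter


@dataclass
class EhhsCurve:
    """EHHS evaluated on the site grid outward from a focal site.

    ``offsets`` are signed bp distances from the focal position (0 first,
    then outward); ``values`` the corresponding EHHS.
    """

    focal_position: int
    offsets_left: np.ndarray
    values_left: np.ndarray
    offsets_right: np.ndarray
    values_right: np.ndarray


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def _standardized(alleles: np.ndarray) -> np.ndarray:
    """Columns standardized to mean 0, SD 1 (monomorphic columns -> NaN)."""
    a = alleles.astype(np.float64)
    p = a.mean(axis=0)
    sd = np.sqrt(p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a - p) / sd


def pairwise_r2(hm: HaplotypeMatrix, i: int, j: int) -> float:
    """Haplotype r² between sites ``i`` and ``j``.

    r² = D² / (pA qA pB qB) with D the haplotype-frequency covariance,
    equivalently the squared Pearson correlation of the two allele columns.
    Monomorphic sites have undefined LD and return NaN.
    """
    a = hm.alleles[:, i].astype(float)
    b = hm.alleles[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        return float("nan")
    if i == j:
        return 1.0
    d = (a * b).mean() - pa * pb
    return float(d * d / (va * vb))


def genotype_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Unphased LD dialect: squared Pearson correlation of dosages.

    Provided for unphased input; the phased haplotype r² is the primary
    definition.
    """
    d = gm.dosages[:, [i, j]].astype(float)
    ok = (d >= 0).all(axis=1)
    d = d[ok]
    if d.shape[0] < 2 or d[:, 0].std() == 0 or d[:, 1].std() == 0:
        return float("nan")
    r = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
    return float(r * r)


def _pair_r2_stream(hm: HaplotypeMatrix, min_sep: int, max_sep: int, min_maf: float):
    """Yield (separation, midpoint, r²) arrays for all eligible site pairs.

    Iterates focal sites and computes r² against all partners within the
    separation band in one vectorized step.
    """
    m = hm.filter_maf(min_maf) if min_maf > 0 else hm
    Z = _standardized(m.alleles)
    pos = m.positions
    n = m.n_hap
    for i in range(m.n_sites - 1):
        lo = np.searchsorted(pos, pos[i] + min_sep, side="left")
        hi = np.searchsorted(pos, pos[i] + max_sep, side="right")
        lo = max(lo, i + 1)
        if hi <= lo:
            continue
        r = Z[:, i] @ Z[:, lo:hi] / n
        yield pos[lo:hi] - pos[i], (pos[lo:hi] + pos[i]) / 2.0, r * r


def ld_decay_curve(
    hm: HaplotypeMatrix,
    max_dist: int = 50_000,
    n_bins: int = 25,
    min_maf: float = 0.05,
    span: float = 0.5,
) -> ScanTrack:
    """Mean r² per (log-spaced) distance bin, with a LOESS smooth over log10
    distance.

    Bins with no eligible pair are reported as NaN, not zero.
    """
    edges = np.geomspace(1, max_dist, n_bins + 1)
    edges[0] = 0.999  # include distance-1 pairs in the first bin
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for sep, _, r2 in _pair_r2_stream(hm, 1, max_dist, min_maf):
        b = np.clip(np.searchsorted(edges, sep, side="right") - 1, 0, n_bins - 1)
        np.add.at(sums, b, r2)
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = np.sqrt(edges[:-1].clip(min=1) * edges[1:])
    ok = np.isfinite(mean_r2)
    smoothed = np.full(n_bins, np.nan)
    if ok.sum() >= 5:
        smoothed[ok] = loess(
            np.log10(centers[ok]), mean_r2[ok], span=span, degree=1
        )
    return ScanTrack(
        "ld_decay",
        centers,
        mean_r2,
        smoothed,
        hm.chrom,
        meta={
            "n_pairs": counts,
            "bin_edges": edges,
            "ld_dialect": "haplotype_r2",
            "x_axis": "pair distance (bp)",
        },
    )


def long_distance_ld_track(
    hm: HaplotypeMatrix,
    window: int = 200_000,
    step: int = 50_000,
    min_sep: int = 20_000,
    max_sep: int = 200_000,
    min_maf: float = 0.05,
) -> ScanTrack:
    """Sliding-window track of mean long-distance r².

    A pair contributes to every window containing its midpoint; pairs are
    eligible when their separation lies in ``[min_sep, max_sep]``.  Windows
    with no eligible pair are NaN.
    """
    L = hm.length
    starts = np.arange(0, max(L - window, 0) + 1, step, dtype=np.int64)
    if starts.size == 0:
        starts = np.array([0], dtype=np.int64)
    nw = starts.size
    sums = np.zeros(nw)
    counts = np.zeros(nw, dtype=np.int64)
    n_overlap = max(window // step, 1)
    for _, mid, r2 in _pair_r2_stream(hm, min_sep, max_sep, min_maf):
        base = (mid // step).astype(np.int64)
        for off in range(n_overlap):
            k = base - off
            ok = (k >= 0) & (k < nw)
            ok &= (mid >= starts[np.clip(k, 0, nw - 1)]) & (
                mid < starts[np.clip(k, 0, nw - 1)] + window
            )
            np.add.at(sums, k[ok], r2[ok])
            np.add.at(counts, k[ok], 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ScanTrack(
        "long_distance_r2",
        starts + window / 2.0,
        mean_r2,
        chrom=hm.chrom,
        window=(window, step),
        meta={
            "n_pairs": counts,
            "min_sep": min_sep,
            "max_sep": max_sep,
            "ld_dialect": "haplotype_r2",
        },
    )


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


def hudson_fst_per_snp(gm: GenotypeMatrix, pop_a, pop_b) -> ScanTrack:
    """Per-SNP Hudson/Bhatia FST between two labelled populations.

    numerator = (p1-p2)² - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    with ``n`` the called allele counts.  Raw values are reported and may be
    negative; sites monomorphic across both populations (or with fewer than
    two called alleles in either) are NaN.
    """
    if gm.pop_labels is None:
        raise ValueError("GenotypeMatrix has no population labels")
    rows_a = np.where(gm.pop_labels == pop_a)[0]
    rows_b = np.where(gm.pop_labels == pop_b)[0]
    if rows_a.size == 0 or rows_b.size == 0:
        raise ValueError(f"empty population among {pop_a!r}, {pop_b!r}")
    ac1, an1 = gm.allele_counts(rows_a)
    ac2, an2 = gm.allele_counts(rows_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / an1
        p2 = ac2 / an2
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (an1 - 1)
            - p2 * (1 - p2) / (an2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    bad = (an1 < 2) | (an2 < 2) | (den == 0)
    fst = np.where(bad, np.nan, fst)
    return ScanTrack(
        "hudson_fst",
        gm.positions.astype(float),
        fst,
        chrom=gm.chrom,
        meta={"pop_a": pop_a, "pop_b": pop_b, "estimator": "hudson_bhatia"},
    )


# ---------------------------------------------------------------------------
# eigenGWAS
# ---------------------------------------------------------------------------


def eigengwas_scan(gm: GenotypeMatrix, k: int = 1, min_maf: float = 0.05) -> EigenGWASResult:
    """Associate each SNP with the leading eigenvector of the genotype
    covariance (eigenGWAS), with median-based genomic control.

    Dosages are standardized by mean ``2p`` and SD ``sqrt(2p(1-p))`` (missing
    values contribute 0 after centering).  The per-SNP statistic is the
    1-df chi-square of the OLS regression of the eigenvector on the SNP;
    lambda_GC = median(chi2) / 0.4549 and corrected p-values use
    chi2 / lambda_GC against a 1-df chi-square.
    """
    if gm.n_ind < 2:
        raise ValueError("need at least 2 individuals")
    d = gm.dosages.astype(np.float64)
    miss = d < 0
    called = ~miss
    with np.errstate(invalid="ignore"):
        p = np.where(miss, 0, d).sum(axis=0) / (2 * called.sum(axis=0))
    maf = np.minimum(p, 1 - p)
    kept = np.where(maf >= min_maf)[0]
    if kept.size < 2:
        raise ValueError("fewer than 2 SNPs after MAF filtering")
    p = p[kept]
    Z = (d[:, kept] - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z[miss[:, kept]] = 0.0
    n, m = Z.shape
    grm = Z @ Z.T / m
    eigvals, eigvecs = np.linalg.eigh(grm)
    scores = eigvecs[:, -1]
    eigenvalues = eigvals[::-1][:k].copy()
    if np.ptp(scores) == 0:
        raise ValueError("leading eigenvector is constant")
    u = (scores - scores.mean())
    u /= u.std()
    Zc = Z - Z.mean(axis=0)
    sd = Zc.std(axis=0)
    sd[sd == 0] = np.inf
    r = (u @ Zc) / (n * sd)
    r2 = np.clip(r * r, 0, 1 - 1e-12)
    chi2 = (n - 2) * r2 / (1 - r2)
    lambda_gc = float(np.median(chi2) / _CHI2_1_MEDIAN)
    p_raw = sps.chi2.sf(chi2, df=1)
    p_gc = sps.chi2.sf(chi2 / lambda_gc, df=1)
    return EigenGWASResult(
        positions=gm.positions[kept].copy(),
        chi2=chi2,
        p_raw=p_raw,
        p_gc=p_gc,
        lambda_gc=lambda_gc,
        scores=scores,
        eigenvalues=eigenvalues,
        kept=kept,
    )


# ---------------------------------------------------------------------------
# extended haplotype homozygosity
# ---------------------------------------------------------------------------


def _homozygosity(codes: np.ndarray) -> float:
    """Probability two distinct haplotypes carry the same group code."""
    n = codes.size
    _, counts = np.unique(codes, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _ehhs_one_direction(alleles, positions, focal, direction):
    """EHHS on the site grid moving outward; returns (|offsets|, values).

    The partition at extent x groups haplotypes by their alleles over the
    closed interval of sites from the focal site to x (the focal alleles
    included); EHHS(0) = 1 by definition and the curve is non-increasing
    outward.
    """
    n_hap, n_sites = alleles.shape
    codes = alleles[:, focal].astype(np.int64)
    offs = [0.0]
    vals = [1.0]
    j = focal + direction
    while 0 <= j < n_sites:
        codes = codes * 2 + alleles[:, j]
        # recode to keep values small
        _, codes = np.unique(codes, return_inverse=True)
        offs.append(abs(float(positions[j] - positions[focal])))
        vals.append(_homozygosity(codes))
        j += direction
    return np.array(offs), np.array(vals)


def ehhs_curve(hm: HaplotypeMatrix, focal: int) -> EhhsCurve:
    """Site EHHS: probability two random haplotypes are identical over the
    closed interval of sites from the focal site out to each position, in
    both directions.

    EHHS(0) = 1 by definition; beyond distance 0 the focal site's own
    alleles enter the partition, and the curve is monotone non-increasing
    with distance.  The focal site must be polymorphic.
    """
    if hm.n_hap < 2:
        raise ValueError("need at least two haplotypes")
    col = hm.alleles[:, focal]
    if col.min() == col.max():
        raise ValueError("focal site is monomorphic")
    ol, vl = _ehhs_one_direction(hm.alleles, hm.positions, focal, -1)
    orr, vr = _ehhs_one_direction(hm.alleles, hm.positions, focal, +1)
    return EhhsCurve(int(hm.positions[focal]), ol, vl, orr, vr)


def _ies_one_side(offs, vals, truncation, extra_beyond_grid):
    """Trapezoid integral of one EHHS branch, truncated at the threshold.

    Integration stops at the last point with EHHS >= truncation; if the curve
    never drops below the threshold it is extended at its final value over the
    remaining ``extra_beyond_grid`` bp to the chromosome edge.
    """
    below = np.where(vals < truncation)[0]
    if below.size:
        stop = below[0]  # index of first sub-threshold point
        o, v = offs[:stop], vals[:stop]
        tail = 0.0
    else:
        o, v = offs, vals
        tail = vals[-1] * extra_beyond_grid
    if o.size < 2:
        return tail
    return float(np.trapezoid(v, o)) + tail


def ies_scan(
    hm: HaplotypeMatrix,
    truncation: float = 0.05,
    per_mb: bool = True,
    use_kernel: bool = True,
) -> ScanTrack:
    """iES per focal site: the trapezoid integral of EHHS over bp in both
    directions, truncated where EHHS < ``truncation`` or at chromosome ends.

    When the curve is still above the threshold at the outermost site it is
    extended at its last value to the chromosome end, so a fully homozygous
    sample integrates to the full chromosome length.  Values are reported per
    Mb.  Monomorphic focal sites are NaN.
    """
    n_sites = hm.n_sites
    out = np.full(n_sites, np.nan)
    if use_kernel:
        try:
            from ._kernels import ies_all_sites

            out = ies_all_sites(
                hm.alleles, hm.positions, float(truncation), int(hm.length)
            )
        except ImportError:  # pragma: no cover - numba always present in CI
            use_kernel = False
    if not use_kernel:
        for s in range(n_sites):
            ol, vl = _ehhs_one_direction(hm.alleles, hm.positions, s, -1)
            orr, vr = _ehhs_one_direction(hm.alleles, hm.positions, s, +1)
            left = _ies_one_side(ol, vl, truncation, float(hm.positions[0]))
            right = _ies_one_side(
                orr, vr, truncation, float(hm.length - hm.positions[-1])
            )
            out[s] = left + right
    # no integrable support on either side: masked
    out[out == 0] = np.nan
    if per_mb:
        out = out / 1e6
    return ScanTrack(
        "ies",
        hm.positions.astype(float),
        out,
        chrom=hm.chrom,
        meta={"truncation": truncation, "units": "EHHS·Mb" if per_mb else "EHHS·bp"},
    )


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def pi_windows(
    hm: HaplotypeMatrix, window: int = 200_000, step: int | None = None
) -> ScanTrack:
    """Windowed nucleotide diversity π per bp.

    π(window) = sum over sites of pairwise differences / C(n,2) / window_bp,
    with monomorphic (absent) sites contributing zero.  Windows are half-open
    ``[start, start+window)``; a final window truncated by the chromosome end
    uses its own length as denominator.
    """
    if step is None:
        step = window
    n = hm.n_hap
    if n < 2:
        raise ValueError("need at least two haplotypes")
    L = hm.length
    c = hm.alleles.sum(axis=0).astype(np.float64)
    site_pi = c * (n - c) / (n * (n - 1) / 2)
    starts = np.arange(0, L, step, dtype=np.int64)
    starts = starts[starts < L]
    raw = np.empty(starts.size)
    mids = np.empty(starts.size)
    cum = np.concatenate([[0.0], np.cumsum(site_pi)])
    for w, s in enumerate(starts):
        e = min(s + window, L)
        i0 = np.searchsorted(hm.positions, s, side="left")
        i1 = np.searchsorted(hm.positions, e, side="left")
        raw[w] = (cum[i1] - cum[i0]) / (e - s)
        mids[w] = (s + e) / 2.0
    return ScanTrack(
        "pi",
        mids,
        raw,
        chrom=hm.chrom,
        window=(window, step),
        meta={"units": "per bp"},
    )


def chromosome_pi(hm: HaplotypeMatrix) -> float:
    """Chromosome-wide π per bp (monomorphic positions count as zero)."""
    n = hm.n_hap
    c = hm.alleles.sum(axis=0).astype(np.float64)
    return float((c * (n - c) / (n * (n - 1) / 2)).sum() / hm.length)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_track(
    track: ScanTrack,
    method: str = "loess",
    span: float | None = None,
    bandwidth: float | None = None,
    degree: int = 2,
    target_window: float = 1e6,
) -> ScanTrack:
    """Return a copy of ``track`` with the ``smoothed`` channel filled.

    Default is LOESS along genome position with the span chosen so the local
    window covers about ``target_window`` bp; ``method='gaussian'`` uses a
    Nadaraya–Watson kernel smoother of SD ``bandwidth`` bp instead.  NaN
    positions are excluded from the fit and get NaN smoothed values.
    """
    ok = np.isfinite(track.raw)
    if ok.sum() < 5:
        raise ValueError("need at least 5 finite points to smooth")
    x, y = track.positions[ok], track.raw[ok]
    smoothed = np.full(track.raw.shape, np.nan)
    if method == "loess":
        if span is None:
            extent = np.ptp(x)
            span = 1.0 if extent == 0 else min(1.0, max(target_window / extent, 0.0))
            span = max(span, (degree + 2) / ok.sum())
        smoothed[ok] = loess(x, y, span=span, degree=degree)
    elif method == "gaussian":
        if bandwidth is None:
            bandwidth = target_window / 4
        smoothed[ok] = gaussian_kernel_smooth(x, y, bandwidth=bandwidth)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return ScanTrack(
        track.statistic,
        track.positions.copy(),
        track.raw.copy(),
        smoothed,
        track.chrom,
        track.window,
        dict(track.meta, smoother=method, span=span, bandwidth=bandwidth),
    )
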
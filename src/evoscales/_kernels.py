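"""Numba inner loops for the forward simulator and the iES scan.

These are performance kernels only; each has a pure-NumPy reference path in
its calling module that defines the semantics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "make_gametes_packed",
    "log_fitness_packed_uniform",
    "log_fitness_packed_cols",
    "count_columns_packed",
    "compact_columns_packed",
    "unpack_rows_packed",
    "ies_all_sites",
]


U64_0 = np.uint64(0)
U64_1 = np.uint64(1)
U64_ALL = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(inline="always")
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(inline="always")
def _or_bit_range(H, src, out, g, start, end):
    """OR bits [start, end) of row ``src`` of H into row ``g`` of out."""
    wa = start >> 6
    wb = (end - 1) >> 6
    for w in range(wa, wb + 1):
        mask = U64_ALL
        if w == wa:
            mask &= U64_ALL << np.uint64(start & 63)
        if w == wb:
            mask &= U64_ALL >> np.uint64(63 - ((end - 1) & 63))
        out[g, w] |= H[src, w] & mask


@njit(cache=True)
def make_gametes_packed(H, pos, m_sorted, m, parents, starts, bp_flat, bp_off, out):
    """Bit-packed gamete construction (see the module docstring of
    forward_sim for the model).

    ``H``/``out``: (2N, n_words) uint64, column ``c`` at word ``c >> 6``,
    bit ``c & 63``.  Columns [0, m_sorted) are sorted by ``pos``; columns
    [m_sorted, m) are the unsorted mutation tail.  Bits at columns >= m are
    zero by invariant and stay zero.
    """
    n_gam = parents.shape[0]
    n_words = (m + 63) >> 6
    sorted_pos = pos[:m_sorted]
    for g in range(n_gam):
        a = 2 * parents[g] + starts[g]
        b = 2 * parents[g] + (1 - starts[g])
        k0, k1 = bp_off[g], bp_off[g + 1]
        k = k1 - k0
        if k == 0:
            for w in range(n_words):
                out[g, w] = H[a, w]
            continue
        # sort this gamete's breakpoints in place (k is small)
        for i in range(k0 + 1, k1):
            v = bp_flat[i]
            j = i - 1
            while j >= k0 and bp_flat[j] > v:
                bp_flat[j + 1] = bp_flat[j]
                j -= 1
            bp_flat[j + 1] = v
        for w in range(n_words):
            out[g, w] = U64_0
        # sorted region: alternating contiguous bit ranges
        cur = a
        seg_start = 0
        for t in range(k0, k1):
            e = np.searchsorted(sorted_pos, bp_flat[t], side="left")
            if e > seg_start:
                _or_bit_range(H, cur, out, g, seg_start, e)
                seg_start = e
            cur = b if cur == a else a
        if m_sorted > seg_start:
            _or_bit_range(H, cur, out, g, seg_start, m_sorted)
        # unsorted tail: per-column breakpoint parity
        for c in range(m_sorted, m):
            cnt = 0
            for t in range(k0, k1):
                if bp_flat[t] <= pos[c]:
                    cnt += 1
            src = b if (cnt & 1) else a
            w = c >> 6
            bit = np.uint64(c & 63)
            out[g, w] |= ((H[src, w] >> bit) & U64_1) << bit


@njit(cache=True)
def log_fitness_packed_uniform(H, selmask, n_words, log_het, log_hom, out):
    """Per-individual log fitness when all deleterious sites share one s.

    Word-parallel: heterozygous selected sites are set bits of
    ``(hapA ^ hapB) & selmask``, homozygous ones of
    ``(hapA & hapB) & selmask``.
    """
    n_ind = H.shape[0] // 2
    for i in range(n_ind):
        n_het = U64_0
        n_hom = U64_0
        for w in range(n_words):
            aw = H[2 * i, w]
            bw = H[2 * i + 1, w]
            sm = selmask[w]
            n_het += _popcount64((aw ^ bw) & sm)
            n_hom += _popcount64((aw & bw) & sm)
        out[i] = n_het * log_het + n_hom * log_hom


@njit(cache=True)
def log_fitness_packed_cols(H, selcols, log_het, log_hom, out):
    """Per-individual log fitness with per-column selection coefficients."""
    n_ind = H.shape[0] // 2
    n_sel = selcols.shape[0]
    for i in range(n_ind):
        acc = 0.0
        for t in range(n_sel):
            c = selcols[t]
            w = c >> 6
            bit = np.uint64(c & 63)
            d = ((H[2 * i, w] >> bit) & U64_1) + ((H[2 * i + 1, w] >> bit) & U64_1)
            if d == U64_1:
                acc += log_het[t]
            elif d == np.uint64(2):
                acc += log_hom[t]
        out[i] = acc


@njit(cache=True)
def count_columns_packed(H, m):
    """Per-column allele counts over all haplotype rows."""
    n_hap = H.shape[0]
    n_words = (m + 63) >> 6
    counts = np.zeros(m, np.int64)
    for r in range(n_hap):
        for w in range(n_words):
            x = H[r, w]
            base = w << 6
            while x != U64_0:
                lsb = x & (~x + U64_1)
                idx = _popcount64(lsb - U64_1)
                counts[base + np.int64(idx)] += 1
                x ^= lsb
    return counts


@njit(cache=True)
def compact_columns_packed(H, out, order):
    """Gather columns ``order`` of H into columns 0..len(order)-1 of out."""
    n_hap = H.shape[0]
    m_new = order.size
    n_words_new = (m_new + 63) >> 6
    for r in range(n_hap):
        for w in range(n_words_new):
            out[r, w] = U64_0
        for j in range(m_new):
            c = order[j]
            if (H[r, c >> 6] >> np.uint64(c & 63)) & U64_1:
                out[r, j >> 6] |= U64_1 << np.uint64(j & 63)


@njit(cache=True)
def unpack_rows_packed(H, rows, m):
    """Unpack selected haplotype rows into a (len(rows), m) uint8 matrix."""
    out = np.zeros((rows.size, m), np.uint8)
    for i in range(rows.size):
        r = rows[i]
        for c in range(m):
            out[i, c] = np.uint8((H[r, c >> 6] >> np.uint64(c & 63)) & U64_1)
    return out


@njit(cache=True)
def _branch_integral(alleles, positions, focal, direction, truncation, edge_extra):
    """Truncated trapezoid integral of one EHHS branch (see popgen_stats)."""
    n_hap, n_sites = alleles.shape
    codes = alleles[:, focal].astype(np.int64)
    relab = np.empty(n_hap, np.int64)
    denom = n_hap * (n_hap - 1)
    prev_off = 0.0
    prev_val = 1.0
    integral = 0.0
    j = focal + direction
    while 0 <= j < n_sites:
        for h in range(n_hap):
            codes[h] = codes[h] * 2 + alleles[h, j]
        order = np.argsort(codes)
        # homozygosity from run lengths of equal codes
        hom_sum = 0
        run = 1
        for t in range(1, n_hap):
            if codes[order[t]] == codes[order[t - 1]]:
                run += 1
            else:
                hom_sum += run * (run - 1)
                run = 1
        hom_sum += run * (run - 1)
        # relabel to 0..n_groups-1 so codes stay small
        lab = 0
        relab[order[0]] = 0
        for t in range(1, n_hap):
            if codes[order[t]] != codes[order[t - 1]]:
                lab += 1
            relab[order[t]] = lab
        codes[:] = relab
        val = hom_sum / denom
        off = abs(float(positions[j] - positions[focal]))
        if val < truncation:
            return integral
        integral += 0.5 * (prev_val + val) * (off - prev_off)
        prev_off = off
        prev_val = val
        if val == 0.0:
            return integral
        j += direction
    return integral + prev_val * edge_extra


@njit(cache=True)
def ies_all_sites(alleles, positions, truncation, length):
    """iES (bp units) for every site; caller masks monomorphic focals."""
    n_sites = alleles.shape[1]
    out = np.empty(n_sites)
    left_extra = float(positions[0]) if n_sites else 0.0
    right_extra = float(length - positions[n_sites - 1]) if n_sites else 0.0
    for s in range(n_sites):
        li = _branch_integral(alleles, positions, s, -1, truncation, left_extra)
        ri = _branch_integral(alleles, positions, s, 1, truncation, right_extra)
        out[s] = li + ri
    return out
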
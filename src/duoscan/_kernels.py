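"""Numba kernels for the two-founder forward simulator.

A chromosome copy is a founder-ancestry mosaic stored as a start label
(``anc0``, 1 = focal founder) plus an ascending list of breakpoint
positions at which ancestry flips; segments are left-closed.  All kernels
operate on flat per-copy arrays: ``anc0 (n_slots,)``, ``nbp (n_slots,)``
and ``bp (n_slots, K)``; the two copies of diploid individual ``i`` live
in slots ``2i`` and ``2i+1`` (slot ``2i+1`` unused for the male X).

Kernels return ``-1`` when a gamete needs more than ``K`` breakpoints so
the caller can grow the buffers and retry with identical randomness.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _merge_gamete(anc0_a, nbp_a, bp_a, anc0_b, nbp_b, bp_b, xo, nxo, start_copy, out_bp):
    """Recombine two parental mosaics at crossovers ``xo[:nxo]`` (ascending).

    Returns ``(start_ancestry, n_breakpoints)`` of the gamete, writing
    breakpoints into ``out_bp``; ``n_breakpoints`` is -1 on overflow.
    """
    K = out_bp.shape[0]
    ia = 0
    ib = 0
    src = start_copy
    if src == 0:
        cur = int(anc0_a)
    else:
        cur = int(anc0_b)
    out0 = cur
    n_out = 0
    for k in range(nxo + 1):
        if k < nxo:
            hi = xo[k]
        else:
            hi = np.inf
        if src == 0:
            while ia < nbp_a and bp_a[ia] < hi:
                if n_out >= K:
                    return 0, -1
                out_bp[n_out] = bp_a[ia]
                n_out += 1
                cur = 1 - cur
                ia += 1
            while ib < nbp_b and bp_b[ib] < hi:
                ib += 1
        else:
            while ib < nbp_b and bp_b[ib] < hi:
                if n_out >= K:
                    return 0, -1
                out_bp[n_out] = bp_b[ib]
                n_out += 1
                cur = 1 - cur
                ib += 1
            while ia < nbp_a and bp_a[ia] < hi:
                ia += 1
        if k < nxo:
            src = 1 - src
            if src == 0:
                new_anc = int(anc0_a) ^ (ia & 1)
            else:
                new_anc = int(anc0_b) ^ (ib & 1)
            if new_anc != cur:
                if n_out >= K:
                    return 0, -1
                out_bp[n_out] = hi
                n_out += 1
                cur = new_anc
    return out0, n_out


@njit(cache=True)
def _sort_slice(x):
    """In-place insertion sort (crossover lists are tiny)."""
    for u in range(1, x.shape[0]):
        v = x[u]
        t = u - 1
        while t >= 0 and x[t] > v:
            x[t + 1] = x[t]
            t -= 1
        x[t + 1] = v


@njit(cache=True)
def make_offspring_autosome(
    anc0, nbp, bp, mo, fa, mo_start, fa_copy, xo_counts, xo_flat,
    new_anc0, new_nbp, new_bp,
):
    """One generation for an autosomal linkage group.

    Mothers transmit a recombined gamete (Drosophila females recombine);
    fathers transmit one whole copy (achiasmatic males).
    """
    n = mo.shape[0]
    off = 0
    for i in range(n):
        c = xo_counts[i]
        xo = xo_flat[off : off + c]
        off += c
        _sort_slice(xo)
        m2 = 2 * mo[i]
        a0, nn = _merge_gamete(
            anc0[m2], nbp[m2], bp[m2],
            anc0[m2 + 1], nbp[m2 + 1], bp[m2 + 1],
            xo, c, mo_start[i], new_bp[2 * i],
        )
        if nn < 0:
            return -1
        new_anc0[2 * i] = a0
        new_nbp[2 * i] = nn
        pc = 2 * fa[i] + fa_copy[i]
        new_anc0[2 * i + 1] = anc0[pc]
        new_nbp[2 * i + 1] = nbp[pc]
        for t in range(nbp[pc]):
            new_bp[2 * i + 1, t] = bp[pc, t]
    return 0


@njit(cache=True)
def make_offspring_x(
    anc0, nbp, bp, mo, fa, mo_start, xo_counts, xo_flat, child_sex,
    new_anc0, new_nbp, new_bp,
):
    """One generation for the X: sons take the mother's X only; daughters
    take a maternal gamete plus the father's single X (his slot ``2*fa``)."""
    n = mo.shape[0]
    off = 0
    for i in range(n):
        c = xo_counts[i]
        xo = xo_flat[off : off + c]
        off += c
        _sort_slice(xo)
        m2 = 2 * mo[i]
        a0, nn = _merge_gamete(
            anc0[m2], nbp[m2], bp[m2],
            anc0[m2 + 1], nbp[m2 + 1], bp[m2 + 1],
            xo, c, mo_start[i], new_bp[2 * i],
        )
        if nn < 0:
            return -1
        new_anc0[2 * i] = a0
        new_nbp[2 * i] = nn
        if child_sex[i] == 0:
            pc = 2 * fa[i]
            new_anc0[2 * i + 1] = anc0[pc]
            new_nbp[2 * i + 1] = nbp[pc]
            for t in range(nbp[pc]):
                new_bp[2 * i + 1, t] = bp[pc, t]
        else:
            new_anc0[2 * i + 1] = 0
            new_nbp[2 * i + 1] = 0
    return 0


@njit(cache=True)
def focal_count_at_markers(anc0, nbp, bp, use, marker_pos, out):
    """Accumulate focal-ancestry copy counts at each sorted marker position."""
    m = marker_pos.shape[0]
    diff = np.zeros(m + 1, np.int64)
    for c in range(anc0.shape[0]):
        if not use[c]:
            continue
        a = int(anc0[c])
        i0 = 0
        for j in range(nbp[c] + 1):
            if j == nbp[c]:
                i1 = m
            else:
                i1 = np.searchsorted(marker_pos, bp[c, j])
            if a == 1 and i1 > i0:
                diff[i0] += 1
                diff[i1] -= 1
            a = 1 - a
            i0 = i1
    acc = 0
    for i in range(m):
        acc += diff[i]
        out[i] += acc


@njit(cache=True)
def ancestry_at_positions(anc0, nbp, bp, positions, out):
    """Per-copy founder ancestry (0/1) at arbitrary positions (for fitness)."""
    for c in range(anc0.shape[0]):
        for t in range(positions.shape[0]):
            k = np.searchsorted(bp[c, : nbp[c]], positions[t])
            out[c, t] = int(anc0[c]) ^ (k & 1)
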
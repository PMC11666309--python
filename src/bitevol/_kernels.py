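"""Numba kernels for the hot decoding path.

Everything here operates on raw uint8 bit arrays and plain numeric arrays so
that a full genome decode (promoter scan on both strands, terminator location,
gene scan, codon translation, phenotype summation) costs tens of microseconds
on kilobase genomes.  The object-level API in :mod:`bitevol.decoder` wraps
these kernels.

Coordinate convention: strand 0 (leading) reads the stored bits left to right;
strand 1 (lagging) reads the complement right to left, so lagging-strand
position ``s`` sits on stored position ``L - 1 - (s mod L)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PROM_LEN = 22
TERM_LEN = 11
GENE_HEAD = 13  # RBS(6) + spacer(4) + START(3)
STOP = 1

# 11-bit popcount table (promoter windows are 22 bits = 2 lookups) and the
# 4-bit reversal table used by the packed terminator predicate.
_POP11 = np.array([bin(i).count("1") for i in range(2048)], dtype=np.uint8)
_REV4 = np.array([int(f"{i:04b}"[::-1], 2) for i in range(16)], dtype=np.uint8)


@njit(cache=True)
def decode_strands(bits, consensus, dmax, w_max):  # pragma: no cover - jitted
    """Scan both strands; return promoter, RNA and protein record arrays.

    Returns
    -------
    prom : (P, 3) int64 — strand, strand-local position, mismatch count
    rna : (R, 5) int64 — strand, transcript start, transcript length,
        promoter row index, terminator strand-local position
    prot_f : (Q, 4) float64 — m, w, h, e
    prot_i : (Q, 4) int64 — strand, CDS start (strand-local, START codon),
        CDS length (START through STOP inclusive), RNA row index
    """
    L = bits.shape[0]
    ext_len = 2 * L + 64
    ext = np.empty(ext_len, np.uint8)
    term = np.empty(L, np.int64)
    codbuf = np.empty(ext_len // 3 + 2, np.uint8)

    cap_pm = 16
    n_pm = 0
    prom = np.empty((cap_pm, 3), np.int64)
    cap_rn = 16
    n_rn = 0
    rna = np.empty((cap_rn, 5), np.int64)
    cap_pr = 16
    n_pr = 0
    prot_f = np.empty((cap_pr, 4), np.float64)
    prot_i = np.empty((cap_pr, 4), np.int64)

    seq = np.empty(L, np.uint8)
    for strand in range(2):
        if strand == 0:
            seq[:] = bits
        else:
            for i in range(L):
                seq[i] = 1 - bits[L - 1 - i]
        if L >= 64:
            ext[:L] = seq
            ext[L : 2 * L] = seq
            ext[2 * L :] = seq[:64]
        else:
            for i in range(ext_len):
                ext[i] = seq[i % L]

        # pack the consensus once (bit j of the window = position i+j)
        cons_packed = 0
        for j in range(PROM_LEN):
            cons_packed |= int(consensus[j]) << j

        # terminator stem-loop positions on this strand (sorted by
        # construction), via an 11-bit sliding window: stem bits 0..3 must be
        # the reversed complement of bits 7..10
        n_t = 0
        w11 = 0
        for j in range(TERM_LEN):
            w11 |= int(ext[j]) << j
        for i in range(L):
            a = w11 & 0xF
            b = (w11 >> 7) & 0xF
            if a == _REV4[(~b) & 0xF]:
                term[n_t] = i
                n_t += 1
            w11 = (w11 >> 1) | (int(ext[i + TERM_LEN]) << (TERM_LEN - 1))

        # promoter scan: 22-bit sliding window + popcount of the XOR
        w22 = 0
        for j in range(PROM_LEN):
            w22 |= int(ext[j]) << j
        for i in range(L):
            diff = w22 ^ cons_packed
            d = _POP11[diff & 0x7FF] + _POP11[(diff >> 11) & 0x7FF]
            w22 = (w22 >> 1) | (int(ext[i + PROM_LEN]) << (PROM_LEN - 1))
            if d > dmax:
                continue
            if n_pm == cap_pm:
                new = np.empty((cap_pm * 2, 3), np.int64)
                new[:cap_pm] = prom
                prom = new
                cap_pm *= 2
            prom[n_pm, 0] = strand
            prom[n_pm, 1] = i
            prom[n_pm, 2] = d
            pm_idx = n_pm
            n_pm += 1

            if n_t == 0:
                continue  # promoter without any reachable terminator: no RNA
            s0 = (i + PROM_LEN) % L
            lo = np.searchsorted(term[:n_t], s0)
            if lo < n_t:
                t = term[lo]
            else:
                t = term[0] + L
            tlen = t - s0 + TERM_LEN
            if n_rn == cap_rn:
                new = np.empty((cap_rn * 2, 5), np.int64)
                new[:cap_rn] = rna
                rna = new
                cap_rn *= 2
            rna[n_rn, 0] = strand
            rna[n_rn, 1] = s0
            rna[n_rn, 2] = tlen
            rna[n_rn, 3] = pm_idx
            rna[n_rn, 4] = t % L
            rn_idx = n_rn
            n_rn += 1

            # gene scan: RBS 011011 + 4-bp spacer + START 000, fully inside
            # the transcript, then codons in frame until STOP.
            jmax = tlen - GENE_HEAD
            end = s0 + tlen
            for j in range(jmax + 1):
                q = s0 + j
                if (
                    ext[q] == 0
                    and ext[q + 1] == 1
                    and ext[q + 2] == 1
                    and ext[q + 3] == 0
                    and ext[q + 4] == 1
                    and ext[q + 5] == 1
                    and ext[q + 10] == 0
                    and ext[q + 11] == 0
                    and ext[q + 12] == 0
                ):
                    r = q + GENE_HEAD
                    n_cod = 0
                    stop_found = False
                    while r + 3 <= end:
                        c = 4 * ext[r] + 2 * ext[r + 1] + ext[r + 2]
                        if c == STOP:
                            stop_found = True
                            break
                        codbuf[n_cod] = c
                        n_cod += 1
                        r += 3
                    if not stop_found or n_cod == 0:
                        continue
                    # Gray-coded binary fractions for m, w, h
                    accm = 0
                    fm = 0.0
                    wtm = 0.5
                    nm = 0
                    accw = 0
                    fw = 0.0
                    wtw = 0.5
                    nw = 0
                    acch = 0
                    fh = 0.0
                    wth = 0.5
                    nh = 0
                    for tt in range(n_cod):
                        c = codbuf[tt]
                        if c >= 6:
                            acch ^= c & 1
                            fh += acch * wth
                            wth *= 0.5
                            nh += 1
                        elif c >= 4:
                            accm ^= c & 1
                            fm += accm * wtm
                            wtm *= 0.5
                            nm += 1
                        elif c >= 2:
                            accw ^= c & 1
                            fw += accw * wtw
                            wtw *= 0.5
                            nw += 1
                        # c == 0 (START inside frame) carries no parameter bits
                    if nm > 0:
                        m = fm / (1.0 - 0.5**nm)
                    else:
                        m = 0.5
                    if nw > 0:
                        w = fw / (1.0 - 0.5**nw) * w_max
                    else:
                        w = 0.0
                    if nh > 0:
                        h = (fh / (1.0 - 0.5**nh)) * 2.0 - 1.0
                    else:
                        h = 0.0
                    if w == 0.0 or h == 0.0:
                        continue  # degenerate kernel: non-functional protein
                    e = 1.0 - d / (dmax + 1.0)
                    if n_pr == cap_pr:
                        newf = np.empty((cap_pr * 2, 4), np.float64)
                        newf[:cap_pr] = prot_f
                        prot_f = newf
                        newi = np.empty((cap_pr * 2, 4), np.int64)
                        newi[:cap_pr] = prot_i
                        prot_i = newi
                        cap_pr *= 2
                    prot_f[n_pr, 0] = m
                    prot_f[n_pr, 1] = w
                    prot_f[n_pr, 2] = h
                    prot_f[n_pr, 3] = e
                    prot_i[n_pr, 0] = strand
                    prot_i[n_pr, 1] = (q + 10) % L
                    prot_i[n_pr, 2] = (r + 3) - (q + 10)
                    prot_i[n_pr, 3] = rn_idx
                    n_pr += 1

    return (
        prom[:n_pm].copy(),
        rna[:n_rn].copy(),
        prot_f[:n_pr].copy(),
        prot_i[:n_pr].copy(),
    )


@njit(cache=True)
def phenotype_and_error(prot_f, order, target):  # pragma: no cover - jitted
    """Sum triangle kernels (in canonical order), clip to [0,1], and return
    (phenotype samples, trapezoidal integral of |phenotype - target|)."""
    D = target.shape[0]
    y = np.zeros(D)
    dm1 = D - 1.0
    for oi in range(order.shape[0]):
        p = order[oi]
        m = prot_f[p, 0]
        w = prot_f[p, 1]
        hh = prot_f[p, 2] * prot_f[p, 3]
        lo = int(np.ceil((m - w) * dm1))
        hi = int(np.floor((m + w) * dm1))
        if lo < 0:
            lo = 0
        if hi > D - 1:
            hi = D - 1
        for i in range(lo, hi + 1):
            x = i / dm1
            y[i] += hh * (1.0 - abs(x - m) / w)
    for i in range(D):
        if y[i] < 0.0:
            y[i] = 0.0
        elif y[i] > 1.0:
            y[i] = 1.0
    g = 0.0
    prev = abs(y[0] - target[0])
    for i in range(1, D):
        cur = abs(y[i] - target[i])
        g += 0.5 * (prev + cur)
        prev = cur
    return y, g / dm1


@njit(cache=True)
def coding_mask(prot_i, L):  # pragma: no cover - jitted
    """Per-position CDS mask (union over translated proteins, both strands)."""
    mask = np.zeros(L, np.uint8)
    for p in range(prot_i.shape[0]):
        strand = prot_i[p, 0]
        start = prot_i[p, 1]
        length = prot_i[p, 2]
        for t in range(length):
            s = (start + t) % L
            if strand == 0:
                mask[s] = 1
            else:
                mask[L - 1 - s] = 1
    return mask
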
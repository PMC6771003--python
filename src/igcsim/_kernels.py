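"""Compiled inner loops of the forward simulator.

Chromosomes are stored packed: one uint64 word holds 8 consecutive sites
(one byte per site, 0 ancestral / 1 derived, little-endian byte order, so
``state.view(np.uint8)`` is the flat per-site view).  A chromosome row is
the concatenation of the five blocks (copy1, spacer1, copy2, spacer2,
copy3), each ``L`` sites, ``L`` a multiple of 8 so every block is
word-aligned.  Copy-presence is tracked in separate uint8 flag arrays; the
site words of an absent block are stale garbage and must never be read,
which the carrier bookkeeping below guarantees.

All randomness inside a kernel comes from numba's thread-local MT19937,
reseeded explicitly at each kernel entry; the driver derives one 31-bit
seed per (run seed, generation, restart attempt) so every generation is
replayable in isolation.
"""

import numpy as np
from numba import njit

U0 = np.uint64(0)
U1 = np.uint64(1)
UFULL = np.uint64(0xFFFFFFFFFFFFFFFF)

# donor / acceptor block index per directed IGC channel
# channels: 1->2, 2->1, 1->3, 3->1, 2->3, 3->2 (copy i lives in block 2(i-1))
_IGC_DONOR = np.array([0, 2, 0, 4, 2, 4], dtype=np.int64)
_IGC_ACC = np.array([2, 0, 4, 0, 4, 2], dtype=np.int64)


@njit(inline="always")
def _copy_bytes(dst, di, src, si, lo, hi, sdelta):
    """Copy byte range [lo, hi) of row ``si`` of ``src`` (offset by ``sdelta``
    words) onto row ``di`` of ``dst`` at the same byte offsets.  ``lo`` and
    ``hi - 1 + 8*sdelta`` must address the same word-alignment class, which
    holds whenever the source/destination byte offsets differ by a multiple
    of 8 (block starts are word-aligned)."""
    if hi <= lo:
        return
    wlo = lo >> 3
    whi = hi >> 3
    olo = lo & 7
    ohi = hi & 7
    if wlo == whi:
        nb = hi - lo
        mask = ((U1 << np.uint64(nb * 8)) - U1) << np.uint64(olo * 8)
        inv = UFULL ^ mask
        dst[di, wlo] = (dst[di, wlo] & inv) | (src[si, wlo + sdelta] & mask)
        return
    w = wlo
    if olo != 0:
        mask = UFULL ^ ((U1 << np.uint64(olo * 8)) - U1)
        inv = UFULL ^ mask
        dst[di, w] = (dst[di, w] & inv) | (src[si, w + sdelta] & mask)
        w += 1
    while w < whi:
        dst[di, w] = src[si, w + sdelta]
        w += 1
    if ohi != 0:
        mask = (U1 << np.uint64(ohi * 8)) - U1
        inv = UFULL ^ mask
        dst[di, whi] = (dst[di, whi] & inv) | (src[si, whi + sdelta] & mask)


@njit(inline="always")
def _set_derived(state, i, j):
    state[i, j >> 3] |= U1 << np.uint64((j & 7) * 8)


@njit(cache=True)
def convert_tract(state, arow, drow, ablk, dblk, start, tract, L):
    """One gene-conversion event: overwrite acceptor block ``ablk`` sites
    [start, start+tract) of row ``arow`` with the donor block's sites,
    truncated at the block end."""
    ln = tract
    if start + ln > L:
        ln = L - start
    lo = ablk * L + start
    sdelta = ((dblk - ablk) * L) >> 3
    _copy_bytes(state, arow, state, drow, lo, lo + ln, sdelta)
    return ln


@njit(inline="always")
def _carriers(flags, out):
    k = 0
    for i in range(flags.shape[0]):
        if flags[i] != 0:
            out[k] = i
            k += 1
    return k


@njit(inline="always")
def _do_igc(state, has2, has3, L, c_eff, frac_cum, tract, pres2, pres3):
    """Draw Poisson(c_eff) conversion events on the current state.  Events
    whose donor or acceptor copy has no carrier are skipped (counted)."""
    skipped = 0
    if c_eff <= 0.0:
        return skipped
    n = state.shape[0]
    n2 = _carriers(has2, pres2)
    n3 = _carriers(has3, pres3)
    k = np.random.poisson(c_eff)
    for _ in range(k):
        u = np.random.random()
        ch = 0
        while ch < 5 and u > frac_cum[ch]:
            ch += 1
        dblk = _IGC_DONOR[ch]
        ablk = _IGC_ACC[ch]
        # donor chromosome among carriers of the donor copy
        if dblk == 0:
            drow = np.random.randint(n)
        elif dblk == 2:
            if n2 == 0:
                skipped += 1
                continue
            drow = pres2[np.random.randint(n2)]
        else:
            if n3 == 0:
                skipped += 1
                continue
            drow = pres3[np.random.randint(n3)]
        if ablk == 0:
            arow = np.random.randint(n)
        elif ablk == 2:
            if n2 == 0:
                skipped += 1
                continue
            arow = pres2[np.random.randint(n2)]
        else:
            if n3 == 0:
                skipped += 1
                continue
            arow = pres3[np.random.randint(n3)]
        start = np.random.randint(L)
        convert_tract(state, arow, drow, ablk, dblk, start, tract, L)
    return skipped


@njit(cache=True)
def igc_only(state, has2, has3, L, c_eff, frac_cum, tract, seed):
    """Apply one generation's worth of IGC events in place (no reproduction)."""
    np.random.seed(seed)
    n = state.shape[0]
    pres2 = np.empty(n, np.int64)
    pres3 = np.empty(n, np.int64)
    return _do_igc(state, has2, has3, L, c_eff, frac_cum, tract, pres2, pres3)


@njit(inline="always")
def _draw_parent(n, weighted, w1, w0, n1, n0, pres2, abs2):
    if not weighted:
        return np.random.randint(n)
    t1 = n1 * w1
    tot = t1 + n0 * w0
    u = np.random.random() * tot
    if u < t1:
        k = int(u / w1)
        if k >= n1:
            k = n1 - 1
        return pres2[k]
    k = int((u - t1) / w0)
    if k >= n0:
        k = n0 - 1
    return abs2[k]


@njit(cache=True)
def _generation_core(state, has2, has3, new_state, new_has2, new_has3,
                     L, pblock, mu, c_eff, frac_cum, tract,
                     sel_on, sel_strength, pres2, abs2, pres3):
    """One generation into ``new_*`` (reproduction, mutation, IGC).  The
    caller must have seeded the RNG.  Returns skipped IGC events, or -1 if
    phase-VI selection weights degenerate to zero total weight."""
    n, W = state.shape
    M = 5 * L

    n1 = 0
    n0 = 0
    for i in range(n):
        if has2[i] != 0:
            pres2[n1] = i
            n1 += 1
        else:
            abs2[n0] = i
            n0 += 1

    # frequency-dependent weights on the two copy2-presence classes
    weighted = False
    w1 = 1.0
    w0 = 1.0
    if sel_on and n1 > 0 and n0 > 0:
        f1 = n1 / n
        w1 = 1.0 + sel_strength * (0.5 - f1)
        w0 = 1.0 + sel_strength * (0.5 - (1.0 - f1))
        if w1 < 0.0:
            w1 = 0.0
        if w0 < 0.0:
            w0 = 0.0
        if n1 * w1 + n0 * w0 <= 0.0:
            return -1
        weighted = True

    # probability that a meiosis has no crossover in any block, used as a
    # one-draw shortcut for the common case
    q_none = 1.0
    for blk in range(5):
        q_none *= 1.0 - pblock[blk]

    cuts = np.empty(5, np.int64)
    for i in range(n):
        a = _draw_parent(n, weighted, w1, w0, n1, n0, pres2, abs2)
        nc = 0
        b = a
        if np.random.random() >= q_none:
            b = _draw_parent(n, weighted, w1, w0, n1, n0, pres2, abs2)
            # sample the crossover pattern conditioned on >= 1 block firing
            fired = 0
            while fired == 0:
                for blk in range(5):
                    p = pblock[blk]
                    if p > 0.0 and np.random.random() < p:
                        fired += 1
                        # structural heterozygosity suppresses crossover: a
                        # pairing discordant for copy2 presence cannot
                        # recombine in the mispaired copy1-spacer1-copy2
                        # cluster, and one discordant for copy3 cannot
                        # recombine inside copy3
                        if blk <= 2 and has2[a] != has2[b]:
                            continue
                        if blk == 4 and has3[a] != has3[b]:
                            continue
                        cuts[nc] = blk * L + np.random.randint(L)
                        nc += 1
        if nc == 0:
            for w in range(W):
                new_state[i, w] = state[a, w]
            new_has2[i] = has2[a]
            new_has3[i] = has3[a]
        else:
            src = a
            prev = 0
            for c in range(nc):
                _copy_bytes(new_state, i, state, src, prev, cuts[c], 0)
                src = b if src == a else a
                prev = cuts[c]
            _copy_bytes(new_state, i, state, src, prev, M, 0)
            k2 = 0
            k3 = 0
            for c in range(nc):
                if cuts[c] <= 2 * L:
                    k2 += 1
                if cuts[c] <= 4 * L:
                    k3 += 1
            new_has2[i] = has2[a] if k2 % 2 == 0 else has2[b]
            new_has3[i] = has3[a] if k3 % 2 == 0 else has3[b]

    # mutation: expected mu per carrier chromosome per block
    n2 = _carriers(new_has2, pres2)
    n3 = _carriers(new_has3, pres3)
    for blk in range(5):
        if blk == 2:
            cnt = n2
        elif blk == 4:
            cnt = n3
        else:
            cnt = n
        if cnt == 0:
            continue
        k = np.random.poisson(mu * cnt)
        for _ in range(k):
            if blk == 2:
                row = pres2[np.random.randint(n2)]
            elif blk == 4:
                row = pres3[np.random.randint(n3)]
            else:
                row = np.random.randint(n)
            _set_derived(new_state, row, blk * L + np.random.randint(L))

    return _do_igc(new_state, new_has2, new_has3, L, c_eff, frac_cum, tract,
                   pres2, pres3)


@njit(cache=True)
def one_generation(state, has2, has3, new_state, new_has2, new_has3,
                   L, pblock, mu, c_eff, frac_cum, tract,
                   sel_on, sel_strength, seed):
    """Single seeded generation step (the public per-step path)."""
    np.random.seed(seed)
    n = state.shape[0]
    pres2 = np.empty(n, np.int64)
    abs2 = np.empty(n, np.int64)
    pres3 = np.empty(n, np.int64)
    return _generation_core(state, has2, has3, new_state, new_has2, new_has3,
                            L, pblock, mu, c_eff, frac_cum, tract,
                            sel_on, sel_strength, pres2, abs2, pres3)


@njit(inline="always")
def _mix64(seed, gen, attempt):
    """31-bit per-generation seed; must match :func:`mix_seed` exactly."""
    x = (np.uint64(seed & 0xFFFFFFFF) * np.uint64(0x9E3779B9)
         + np.uint64(gen) * np.uint64(0x85EBCA6B)
         + np.uint64(attempt) * np.uint64(0xC2B2AE35)
         + np.uint64(0x27D4EB2F))
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return np.int64(x & np.uint64(0x7FFFFFFF))


@njit(cache=True)
def run_gens(state, has2, has3, buf_state, buf_has2, buf_has3,
             L, pblock, mu, c_eff, frac_cum, tract,
             sel_on, sel_strength, run_seed, gen0, attempt, ngens,
             watch, thin, rec):
    """Run up to ``ngens`` generations in one compiled loop.

    Each generation g is seeded with ``_mix64(run_seed, g, attempt)``, so
    the trajectory is identical to stepping one generation at a time.  When
    ``thin > 0``, per-block pi and the copy2 frequency are written into
    ``rec[g // thin]`` whenever g is a multiple of ``thin``.

    ``watch`` = 0 (none), 2 or 3: after each generation count the carriers
    of copy2 or copy3 and stop early on absorption.  Returns
    (status, gens_done, skipped_igc) with status 0 = ran to ngens,
    1 = watched copy lost, 2 = watched copy fixed, -1 = degenerate
    selection weights.  The final state is always left in ``state``/
    ``has2``/``has3``.
    """
    n, W = state.shape
    pres2 = np.empty(n, np.int64)
    abs2 = np.empty(n, np.int64)
    pres3 = np.empty(n, np.int64)
    cur_s, cur_h2, cur_h3 = state, has2, has3
    new_s, new_h2, new_h3 = buf_state, buf_has2, buf_has3
    status = 0
    done = 0
    skipped = 0
    for i in range(ngens):
        g = gen0 + i + 1
        np.random.seed(_mix64(run_seed, g, attempt))
        rc = _generation_core(cur_s, cur_h2, cur_h3, new_s, new_h2, new_h3,
                              L, pblock, mu, c_eff, frac_cum, tract,
                              sel_on, sel_strength, pres2, abs2, pres3)
        if rc < 0:
            status = -1
            break
        skipped += rc
        ts, th2, th3 = cur_s, cur_h2, cur_h3
        cur_s, cur_h2, cur_h3 = new_s, new_h2, new_h3
        new_s, new_h2, new_h3 = ts, th2, th3
        done = i + 1
        if thin > 0 and g % thin == 0:
            idx = g // thin
            if idx < rec.shape[0]:
                record_stats(cur_s, cur_h2, cur_h3, L, rec[idx])
        if watch == 2 or watch == 3:
            flags = cur_h2 if watch == 2 else cur_h3
            k = 0
            for j in range(n):
                k += flags[j]
            if k == 0:
                status = 1
                break
            if k == n:
                status = 2
                break
    if done % 2 == 1:
        # final generation lives in the scratch buffer: copy it back
        for i in range(n):
            for w in range(W):
                state[i, w] = cur_s[i, w]
            has2[i] = cur_h2[i]
            has3[i] = cur_h3[i]
    return status, done, skipped


@njit(cache=True)
def block_pi(state, rows, nrows, blk, L):
    """Mean pairwise per-site diversity of one block over carrier rows."""
    if nrows < 2:
        return np.nan
    base = (blk * L) >> 3
    Wb = L >> 3
    cnt = np.zeros(L, np.int64)
    for r in range(nrows):
        i = rows[r]
        for w in range(Wb):
            v = state[i, base + w]
            for b in range(8):
                cnt[w * 8 + b] += (v >> np.uint64(b * 8)) & U1
    tot = 0.0
    for j in range(L):
        c = cnt[j]
        tot += 2.0 * c * (nrows - c)
    return tot / (nrows * (nrows - 1.0)) / L


@njit(cache=True)
def record_stats(state, has2, has3, L, out):
    """Fill ``out`` (length 6) with per-block pi (NaN if <2 carriers) and
    the copy2 carrier frequency."""
    n = state.shape[0]
    allrows = np.empty(n, np.int64)
    for i in range(n):
        allrows[i] = i
    pres2 = np.empty(n, np.int64)
    pres3 = np.empty(n, np.int64)
    n2 = _carriers(has2, pres2)
    n3 = _carriers(has3, pres3)
    out[0] = block_pi(state, allrows, n, 0, L)
    out[1] = block_pi(state, allrows, n, 1, L)
    out[2] = block_pi(state, pres2, n2, 2, L)
    out[3] = block_pi(state, allrows, n, 3, L)
    out[4] = block_pi(state, pres3, n3, 4, L)
    out[5] = n2 / n


def mix_seed(seed: int, gen: int, attempt: int = 0) -> int:
    """Derive a 31-bit kernel seed from (run seed, generation, attempt)."""
    x = ((seed & 0xFFFFFFFF) * 0x9E3779B9 + gen * 0x85EBCA6B
         + attempt * 0xC2B2AE35 + 0x27D4EB2F) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 30
    x = (x * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 27
    x = (x * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 31
    return x & 0x7FFFFFFF
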
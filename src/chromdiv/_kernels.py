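"""Numba kernels for the array-based Wright-Fisher engine.

The population is a dense genotype-incidence matrix ``H`` of shape
``(2N, capacity)`` (uint8): row = haplotype, column = segregating mutation.
Parallel arrays ``pos``/``sval``/``ids`` carry each column's bp position,
selection coefficient and run-unique mutation id.  Columns are unordered;
gametes are built per offspring by tossing crossover/gene-conversion
breakpoints and resolving, per column, which parental haplotype the site is
inherited from.  Lost columns are dropped and fixed columns are moved to a
per-population substitution ledger during periodic compaction (removing a
fixed column rescales every individual's fitness by the same constant, so
selection is unaffected).

Status codes returned by :func:`run_epoch`:
0 = ran to completion; 1 = column capacity exhausted (caller grows arrays
and resumes); 2 = population extinct (all fitness weights zero);
3 = substitution-ledger capacity exhausted.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_GROW_SITES = 1
STATUS_EXTINCT = 2
STATUS_GROW_SUBS = 3

# hard cap on per-gamete breakpoint buffers; Poisson means here are <~1 so
# 64 events in one meiosis is unreachable in practice
_MAX_EVENTS = 64


@njit(cache=True)
def _compact(H, pos, sval, ids, n_sites, n_haps, sub_pos, sub_s, sub_ids, n_subs):
    """Drop lost columns, move fixed columns to the substitution ledger.

    Returns (new_n_sites, new_n_subs, overflow_flag).
    """
    cnt = np.zeros(n_sites, dtype=np.int64)
    for r in range(n_haps):
        row = H[r]
        for c in range(n_sites):
            cnt[c] += row[c]
    keep = np.empty(n_sites, dtype=np.int64)
    nk = 0
    for c in range(n_sites):
        if cnt[c] == 0:
            continue
        if cnt[c] == n_haps:
            if n_subs >= sub_pos.shape[0]:
                return n_sites, n_subs, True
            sub_pos[n_subs] = pos[c]
            sub_s[n_subs] = sval[c]
            sub_ids[n_subs] = ids[c]
            n_subs += 1
            continue
        keep[nk] = c
        nk += 1
    # in-place column compaction; keep[k] >= k so forward copy is safe
    for r in range(n_haps):
        row = H[r]
        for k in range(nk):
            row[k] = row[keep[k]]
    for k in range(nk):
        kk = keep[k]
        pos[k] = pos[kk]
        sval[k] = sval[kk]
        ids[k] = ids[kk]
    return nk, n_subs, False


@njit(cache=True)
def _log_fitness(H, sval, n_sites, N, lw):
    """Multiplicative codominant fitness, accumulated in log space.

    w_i = prod over selected loci of (1+s) if homozygous, (1+s/2) if
    heterozygous, floored at zero.
    """
    n_sel = 0
    sel = np.empty(n_sites, dtype=np.int64)
    lhet = np.empty(n_sites, dtype=np.float64)
    lhom = np.empty(n_sites, dtype=np.float64)
    for c in range(n_sites):
        s = sval[c]
        if s != 0.0:
            sel[n_sel] = c
            x = 1.0 + 0.5 * s
            lhet[n_sel] = np.log(x) if x > 0.0 else -1e300
            x = 1.0 + s
            lhom[n_sel] = np.log(x) if x > 0.0 else -1e300
            n_sel += 1
    for i in range(N):
        acc = 0.0
        rowa = H[2 * i]
        rowb = H[2 * i + 1]
        for k in range(n_sel):
            c = sel[k]
            g = rowa[c] + rowb[c]
            if g == 1:
                acc += lhet[k]
            elif g == 2:
                acc += lhom[k]
        lw[i] = acc


@njit(cache=True)
def _pick_parent(wcum, wtot):
    u = np.random.random() * wtot
    lo = 0
    hi = wcum.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if wcum[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def run_epoch(
    H,
    HB,
    pos,
    sval,
    ids,
    n_sites,
    L,
    exp_crossovers,
    exp_gc_initiations,
    gc_tract_mean,
    gc_fixed_tract,
    mu_L,
    cod_starts,
    cod_ends,
    p_neutral,
    p_deleterious,
    dfe_shape,
    dfe_scale,
    selection,
    sub_pos,
    sub_s,
    sub_ids,
    n_subs,
    next_id,
    n_gens,
    compact_every,
    seed,
):
    """Advance the population ``n_gens`` Wright-Fisher generations in place.

    On return the live state is always in ``H`` (the scratch buffer ``HB``
    holds garbage).  Returns
    ``(n_sites, n_subs, next_id, gens_done, status)``.
    """
    np.random.seed(seed)
    n_haps = H.shape[0]
    N = n_haps // 2
    cap = H.shape[1]
    n_genes = cod_starts.shape[0]

    lw = np.empty(N, dtype=np.float64)
    wcum = np.empty(N, dtype=np.float64)
    ev = np.empty(_MAX_EVENTS, dtype=np.int64)

    # worst-case new columns per generation (Poisson tail margin)
    mean_new = mu_L * n_haps
    margin = np.int64(mean_new + 6.0 * np.sqrt(mean_new + 1.0) + 16.0)
    new_row = np.empty(margin, dtype=np.int64)
    new_col = np.empty(margin, dtype=np.int64)

    in_primary = True
    gens_done = 0
    status = STATUS_OK

    for g in range(n_gens):
        cur = H if in_primary else HB
        nxt = HB if in_primary else H

        if n_sites + margin > cap or (compact_every > 0 and g % compact_every == 0):
            n_sites, n_subs, overflow = _compact(
                cur, pos, sval, ids, n_sites, n_haps, sub_pos, sub_s, sub_ids, n_subs
            )
            if overflow:
                status = STATUS_GROW_SUBS
                break
            if n_sites + margin > cap:
                status = STATUS_GROW_SITES
                break

        wtot = 0.0
        if selection:
            _log_fitness(cur, sval, n_sites, N, lw)
            lwmax = lw[0]
            for i in range(1, N):
                if lw[i] > lwmax:
                    lwmax = lw[i]
            acc = 0.0
            for i in range(N):
                acc += np.exp(lw[i] - lwmax)
                wcum[i] = acc
            wtot = acc
            if wtot <= 0.0 or lwmax <= -1e299:
                status = STATUS_EXTINCT
                break

        base = n_sites
        n_new = 0
        for j in range(n_haps):
            if selection:
                p = _pick_parent(wcum, wtot)
            else:
                p = np.random.randint(0, N)
            h0 = 2 * p
            if np.random.random() < 0.5:
                h0 += 1
            h1 = 2 * p + (1 - (h0 - 2 * p))

            kx = np.random.poisson(exp_crossovers)
            kg = 0
            if exp_gc_initiations > 0.0:
                kg = np.random.poisson(exp_gc_initiations)
            n_ev = 0
            for _ in range(kx):
                if n_ev < _MAX_EVENTS:
                    ev[n_ev] = np.random.randint(0, L)
                    n_ev += 1
            for _ in range(kg):
                if n_ev + 1 < _MAX_EVENTS:
                    st = np.random.randint(0, L)
                    if gc_fixed_tract:
                        tl = np.int64(gc_tract_mean)
                    else:
                        tl = np.random.geometric(1.0 / gc_tract_mean)
                    # a conversion tract toggles the source at entry and exit
                    ev[n_ev] = st
                    ev[n_ev + 1] = st + tl
                    n_ev += 2

            row_nxt = nxt[j]
            if n_ev == 0:
                row_src = cur[h0]
                for c in range(base):
                    row_nxt[c] = row_src[c]
            else:
                # the two parental rows agree at all homozygous columns, so
                # breakpoint parity only needs resolving where they differ
                row0 = cur[h0]
                row1 = cur[h1]
                for c in range(base):
                    v = row0[c]
                    w = row1[c]
                    if v != w:
                        pc = pos[c]
                        parity = 0
                        for t in range(n_ev):
                            if ev[t] <= pc:
                                parity ^= 1
                        if parity:
                            v = w
                    row_nxt[c] = v

            # de novo mutations on this gamete (columns registered now,
            # matrix bits written in one batched pass below)
            nm = np.random.poisson(mu_L)
            for _ in range(nm):
                mp = np.random.randint(0, L)
                ms = 0.0
                if selection:
                    coding = False
                    for gidx in range(n_genes):
                        if cod_starts[gidx] <= mp < cod_ends[gidx]:
                            coding = True
                            break
                    if coding:
                        u = np.random.random()
                        if u < p_neutral:
                            ms = 0.0
                        elif u < p_neutral + p_deleterious:
                            ms = -np.random.gamma(dfe_shape, dfe_scale)
                        else:
                            ms = np.random.gamma(dfe_shape, dfe_scale)
                if n_new >= new_row.shape[0]:
                    continue  # beyond the 6-sigma margin; vanishingly rare
                col = n_sites
                new_row[n_new] = j
                new_col[n_new] = col
                n_new += 1
                pos[col] = mp
                sval[col] = ms
                ids[col] = next_id
                next_id += 1
                n_sites += 1

        # zero the freshly appended columns row-contiguously, then set carriers
        if n_new > 0:
            for r in range(n_haps):
                row = nxt[r]
                for c in range(base, n_sites):
                    row[c] = 0
            for k in range(n_new):
                nxt[new_row[k]][new_col[k]] = 1

        in_primary = not in_primary
        gens_done += 1

    cur = H if in_primary else HB
    n_sites, n_subs, overflow = _compact(
        cur, pos, sval, ids, n_sites, n_haps, sub_pos, sub_s, sub_ids, n_subs
    )
    if overflow and status == STATUS_OK:
        status = STATUS_GROW_SUBS
    if not in_primary:
        for r in range(n_haps):
            src = HB[r]
            dst = H[r]
            for c in range(n_sites):
                dst[c] = src[c]
    return n_sites, n_subs, next_id, gens_done, status
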
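"""Numba kernel for macroscale tPA transport on the clot lattice.

Discrete tPA molecules hop between lattice nodes (fixed step, six directions,
periodic in x and y, reflecting in z) or bind adjacent fibrin edges.  Edge
state is a single float per edge: the scheduled lysis time (+inf while intact
and unscheduled); an edge is degraded once the simulation clock passes it.
Bound molecules release when their residence draw expires or their edge
degrades, whichever comes first.

All arrays are caller-owned; the kernel allocates nothing.
"""

import numpy as np
from numba import njit


@njit
def _seed_rng(seed):
    np.random.seed(seed)


@njit
def _candidate(k, x, z, nx, nzc):
    """k-th potentially adjacent edge of node (x, z): (etype, ex, ez).

    etype -1 marks an invalid slot.  Edge types: 0 = x-edge at (x, z),
    1 = y-edge (periodic slab, one pore deep), 2 = z-edge between levels
    (z, z+1).  Fibrin exists only at levels z < nzc.
    """
    if z < nzc:
        if k == 0:
            return 0, x, z
        if k == 1:
            return 0, (x - 1) % nx, z
        if k == 2:
            return 1, x, z
        if k == 3:
            if z <= nzc - 2:
                return 2, x, z
            return -1, 0, 0
        if z >= 1:
            return 2, x, z - 1
    return -1, 0, 0


@njit
def advance(
    px,
    pz,
    btype,
    bx,
    bz,
    tleave,
    dispx,
    dispy,
    dispz,
    lex,
    ley,
    lez,
    nx,
    nzc,
    nz_total,
    pore,
    t0,
    dt,
    n_steps,
    p_bind,
    res_vals,
    p_lyse,
    delay_vals,
    schedule_mode,
):
    """Advance every particle ``n_steps`` fixed steps from time ``t0``."""
    t = t0
    n_part = px.shape[0]
    n_res = res_vals.shape[0]
    n_del = delay_vals.shape[0]
    for _ in range(n_steps):
        t += dt
        for i in range(n_part):
            bt = btype[i]
            if bt >= 0:
                if bt == 0:
                    elys = lex[bx[i], bz[i]]
                elif bt == 1:
                    elys = ley[bx[i], bz[i]]
                else:
                    elys = lez[bx[i], bz[i]]
                if elys <= t or tleave[i] <= t:
                    btype[i] = -1  # released at its node, no memory
                continue
            x = px[i]
            z = pz[i]
            cnt = 0
            for k in range(5):
                et, cx, cz = _candidate(k, x, z, nx, nzc)
                if et < 0:
                    continue
                if et == 0:
                    elys = lex[cx, cz]
                elif et == 1:
                    elys = ley[cx, cz]
                else:
                    elys = lez[cx, cz]
                if elys > t:
                    cnt += 1
            if cnt > 0 and np.random.random() < p_bind:
                j = int(np.random.random() * cnt)
                if j >= cnt:
                    j = cnt - 1
                for k in range(5):
                    et, cx, cz = _candidate(k, x, z, nx, nzc)
                    if et < 0:
                        continue
                    if et == 0:
                        elys = lex[cx, cz]
                    elif et == 1:
                        elys = ley[cx, cz]
                    else:
                        elys = lez[cx, cz]
                    if elys > t:
                        if j == 0:
                            btype[i] = et
                            bx[i] = cx
                            bz[i] = cz
                            r = int(np.random.random() * n_res)
                            if r >= n_res:
                                r = n_res - 1
                            tleave[i] = t + res_vals[r]
                            if n_del > 0 and np.random.random() < p_lyse:
                                r = int(np.random.random() * n_del)
                                if r >= n_del:
                                    r = n_del - 1
                                tl = t + delay_vals[r]
                                # schedule_mode 0: edge degrades at the earliest
                                # of all draws; 1: the first draw sticks
                                if et == 0:
                                    if tl < lex[cx, cz] and (
                                        schedule_mode == 0 or lex[cx, cz] == np.inf
                                    ):
                                        lex[cx, cz] = tl
                                elif et == 1:
                                    if tl < ley[cx, cz] and (
                                        schedule_mode == 0 or ley[cx, cz] == np.inf
                                    ):
                                        ley[cx, cz] = tl
                                else:
                                    if tl < lez[cx, cz] and (
                                        schedule_mode == 0 or lez[cx, cz] == np.inf
                                    ):
                                        lez[cx, cz] = tl
                            break
                        j -= 1
            else:
                move = int(np.random.random() * 6.0)
                if move == 0:
                    px[i] = (x + 1) % nx
                    dispx[i] += pore
                elif move == 1:
                    px[i] = (x - 1) % nx
                    dispx[i] -= pore
                elif move == 2:
                    dispy[i] += pore  # periodic slab, one pore deep
                elif move == 3:
                    dispy[i] -= pore
                elif move == 4:
                    if z < nz_total - 1:
                        pz[i] = z + 1
                        dispz[i] += pore
                else:
                    if z > 0:
                        pz[i] = z - 1
                        dispz[i] -= pore
    return t
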
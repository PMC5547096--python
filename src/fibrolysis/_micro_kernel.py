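"""Numba kernel for the single-fiber cross-section Gillespie simulation.

State layout (one fiber cross-section, n x n binding locations, 6 binding
doublets each):

* ``exposed[L,6]``  0 cryptic / 1 exposed           (one-way 0 -> 1)
* ``fstate[L,6]``   0 intact / 1 nicked / 2 degraded (one-way, monotone)
* ``plg[L,6]``, ``pli[L,6]`` occupancy flags (a doublet holds at most one
  molecule of each species; tPA position is tracked separately since there
  is exactly one tPA per run)
* ``accessible[L]`` locations reachable by solution-phase plasminogen:
  the perimeter plus 4-neighbors of fully degraded locations.

Per-location integer counters (``C[L, :]`` columns below) and global integer
tallies (``G[:]``) are maintained incrementally so that every propensity is
O(1) to compute and event selection is a single O(L) scan.  Integer counters
cannot drift; a full recount at termination cross-checks the bookkeeping and
is surfaced in the result vector.
"""

import numpy as np
from numba import njit

from .kinetics import (
    R_CAT_AP,
    R_CAT_N,
    R_CRAWL_PLI,
    R_DEG,
    R_OFF_PLG,
    R_OFF_TPA_WITH_PLG,
    R_OFF_TPA_WITHOUT_PLG,
    R_ON_PLG_INTACT,
    R_ON_PLG_NICKED,
    R_PLG_CONC,
    R_UNBIND_PLI,
)

# C columns
PLGC = 0  # bound PLG at location
PLIC = 1  # bound PLi at location
CRY = 2  # cryptic, non-degraded doublets
NOND = 3  # non-degraded doublets
ELI = 4  # doublets eligible for PLG binding, intact
ELN = 5  # doublets eligible for PLG binding, nicked

# G entries
G_ELI = 0
G_ELN = 1
G_PLG = 2
G_PLI = 3
G_EXPO = 4  # sum over locations of PLIC * CRY
G_DEG = 5  # sum over locations of PLIC * NOND

# result vector layout
RES_LEAVE_T = 0
RES_MODE = 1  # 0 kinetic, 1 forced, -1 never left (censored or stalled)
RES_PLI_CREATED = 2
RES_LYSED = 3
RES_LYSIS_T = 4
RES_CENSORED = 5
RES_NEVENTS = 6
RES_TEND = 7
RES_PLG_INTEG = 8  # time integral of bound-PLG count (occupancy oracle)
RES_OK = 9  # 1 if final counter recount matches incremental bookkeeping
RES_CHECK = 10  # event-log checksum (determinism witness)
RES_SEED = 11
N_RES = 12

MODE_KINETIC = 0.0
MODE_FORCED = 1.0
MODE_SEVERED = 2.0  # cross-section transected with the tPA still bound


@njit
def _pick_crawl_target(loc, n, exposed, fstate, pli, allow_cryptic):
    """Uniform choice among non-degraded, PLi-free doublets at the location
    itself or its 4-neighbors; targets must be exposed unless
    ``allow_cryptic`` (a crawling plasmin can bind the fresh lysines of a
    still-cryptic doublet, exposing it).  (-1, -1) if none exists."""
    rr = loc // n
    cc = loc % n
    cnt = 0
    for k5 in range(5):
        if k5 == 0:
            tl = loc
        elif k5 == 1:
            tl = loc - n if rr > 0 else -1
        elif k5 == 2:
            tl = loc + n if rr < n - 1 else -1
        elif k5 == 3:
            tl = loc - 1 if cc > 0 else -1
        else:
            tl = loc + 1 if cc < n - 1 else -1
        if tl < 0:
            continue
        for td in range(6):
            if (
                (exposed[tl, td] == 1 or allow_cryptic)
                and fstate[tl, td] < 2
                and pli[tl, td] == 0
            ):
                cnt += 1
    if cnt == 0:
        return -1, -1
    m = int(np.random.random() * cnt)
    if m >= cnt:
        m = cnt - 1
    for k5 in range(5):
        if k5 == 0:
            tl = loc
        elif k5 == 1:
            tl = loc - n if rr > 0 else -1
        elif k5 == 2:
            tl = loc + n if rr < n - 1 else -1
        elif k5 == 3:
            tl = loc - 1 if cc > 0 else -1
        else:
            tl = loc + 1 if cc < n - 1 else -1
        if tl < 0:
            continue
        for td in range(6):
            if (
                (exposed[tl, td] == 1 or allow_cryptic)
                and fstate[tl, td] < 2
                and pli[tl, td] == 0
            ):
                if m == 0:
                    return tl, td
                m -= 1
    return -1, -1


@njit
def _expose_doublet(loc, d, fstate, exposed, plg, accessible, loc_nicked, C, G):
    """Cryptic -> exposed for one non-degraded doublet, with nick trigger."""
    C[loc, CRY] -= 1
    G[G_EXPO] -= C[loc, PLIC]
    if loc_nicked[loc] == 0:
        loc_nicked[loc] = 1
        _nick_location(loc, fstate, exposed, plg, accessible, C, G)
    exposed[loc, d] = 1
    if accessible[loc] == 1 and plg[loc, d] == 0 and fstate[loc, d] < 2:
        if fstate[loc, d] == 0:
            C[loc, ELI] += 1
            G[G_ELI] += 1
        else:
            C[loc, ELN] += 1
            G[G_ELN] += 1


@njit
def _nick_location(loc, fstate, exposed, plg, accessible, C, G):
    """Intact -> nicked for every non-degraded doublet at a location."""
    for d in range(6):
        if fstate[loc, d] == 0:
            fstate[loc, d] = 1
            if accessible[loc] == 1 and exposed[loc, d] == 1 and plg[loc, d] == 0:
                C[loc, ELI] -= 1
                C[loc, ELN] += 1
                G[G_ELI] -= 1
                G[G_ELN] += 1


@njit
def _make_accessible(loc, fstate, exposed, plg, accessible, C, G):
    if accessible[loc] == 1:
        return
    accessible[loc] = 1
    for d in range(6):
        if exposed[loc, d] == 1 and fstate[loc, d] < 2 and plg[loc, d] == 0:
            if fstate[loc, d] == 0:
                C[loc, ELI] += 1
                G[G_ELI] += 1
            else:
                C[loc, ELN] += 1
                G[G_ELN] += 1


@njit
def _transected(fully_deg, n, stack, seen):
    """True if severed locations connect opposite sides (8-connectivity).

    Checked in both directions: a left-right or top-bottom contiguous band of
    severed locations (diagonal contact included) means the cross-section no
    longer transmits force and the fiber is cut.
    """
    for axis in range(2):
        for i in range(n * n):
            seen[i] = 0
        top = 0
        for i in range(n):
            loc = i * n if axis == 0 else i  # col 0 / row 0
            if fully_deg[loc] == 1 and seen[loc] == 0:
                seen[loc] = 1
                stack[top] = loc
                top += 1
        while top > 0:
            top -= 1
            loc = stack[top]
            r = loc // n
            c = loc % n
            if (axis == 0 and c == n - 1) or (axis == 1 and r == n - 1):
                return True
            for k in range(8):
                if k == 0:
                    rr, cc = r - 1, c
                elif k == 1:
                    rr, cc = r + 1, c
                elif k == 2:
                    rr, cc = r, c - 1
                elif k == 3:
                    rr, cc = r, c + 1
                elif k == 4:
                    rr, cc = r - 1, c - 1
                elif k == 5:
                    rr, cc = r - 1, c + 1
                elif k == 6:
                    rr, cc = r + 1, c - 1
                else:
                    rr, cc = r + 1, c + 1
                if 0 <= rr < n and 0 <= cc < n:
                    nb = rr * n + cc
                    if fully_deg[nb] == 1 and seen[nb] == 0:
                        seen[nb] = 1
                        stack[top] = nb
                        top += 1
    return False


@njit
def micro_ssa(
    n,
    rates,
    seed,
    t_max,
    require_full_grid,
    spare_own,
    cut_threshold,
    relocate_displaced,
    crawl_opens_cryptic,
    stop_at_lysis,
    exposed,
    fstate,
    plg,
    pli,
    accessible,
    loc_nicked,
    fully_deg,
    C,
    G,
    stack,
    seen,
    perim,
    out,
):
    """One microscale run: a single tPA on a fresh cross-section.

    Exact SSA over the eight reaction classes.  Terminates when (a) the tPA
    has left and no plasmin remains, (b) the cross-section is lysed
    (transection by default, full-grid degradation if ``require_full_grid``),
    or (c) ``t_max``.  Runs that still hold the tPA at ``t_max`` are censored.

    A degradation event targets any non-degraded doublet at the plasmin's
    location, including the plasmin's own: cleavage exposes fresh C-terminal
    lysines, so a plasmin whose doublet is degraded rebinds a nearby eligible
    doublet immediately (same target rule as a crawl) and is lost to
    alpha2-antiplasmin only if no such doublet exists.
    """
    L = n * n
    # caller-owned workspace; reset here so it can be reused across runs
    for loc in range(L):
        accessible[loc] = 0
        loc_nicked[loc] = 0
        fully_deg[loc] = 0
        for d in range(6):
            exposed[loc, d] = 0
            fstate[loc, d] = 0
            plg[loc, d] = 0
            pli[loc, d] = 0
            C[loc, d] = 0
    for i in range(6):
        G[i] = 0
    for i in range(N_RES):
        out[i] = 0.0

    np.random.seed(seed)

    # one exposed doublet (index 0) per location; perimeter accessible
    n_perim = 4 * n - 4
    k = 0
    for loc in range(L):
        exposed[loc, 0] = 1
        C[loc, CRY] = 5
        C[loc, NOND] = 6
        r = loc // n
        c = loc % n
        if r == 0 or r == n - 1 or c == 0 or c == n - 1:
            accessible[loc] = 1
            C[loc, ELI] = 1
            G[G_ELI] += 1
            perim[k] = loc
            k += 1

    # single tPA on a uniformly random perimeter location's exposed doublet
    j = int(np.random.random() * n_perim)
    if j >= n_perim:
        j = n_perim - 1
    tpa_loc = perim[j]
    tpa_dbl = 0
    tpa_present = True

    kdeg = rates[R_DEG]
    koff_plg = rates[R_OFF_PLG]
    a_on_i = rates[R_ON_PLG_INTACT] * rates[R_PLG_CONC]
    a_on_n = rates[R_ON_PLG_NICKED] * rates[R_PLG_CONC]
    kcrawl = rates[R_CRAWL_PLI]
    kunb = rates[R_UNBIND_PLI]
    kw = rates[R_OFF_TPA_WITH_PLG]
    kwo = rates[R_OFF_TPA_WITHOUT_PLG]
    kcat_ap = rates[R_CAT_AP]
    kcat_n = rates[R_CAT_N]

    t = 0.0
    integ_plg = 0.0
    n_events = 0
    plasmin_created = 0
    n_fully = 0
    lysed = False
    lysis_t = 0.0
    censored = False
    leave_t = -1.0
    mode = -1.0
    checksum = np.int64(seed) % np.int64(2147483647)
    anomaly = 0

    while True:
        if (not tpa_present) and G[G_PLI] == 0:
            break
        a1i = a_on_i * G[G_ELI]
        a1n = a_on_n * G[G_ELN]
        a2 = koff_plg * G[G_PLG]
        if tpa_present:
            a3 = kw if plg[tpa_loc, tpa_dbl] == 1 else kwo
            a4 = kcat_ap * C[tpa_loc, PLGC]
        else:
            a3 = 0.0
            a4 = 0.0
        a5 = kcat_n * G[G_EXPO]
        deg_pairs = G[G_DEG] - G[G_PLI] if spare_own else G[G_DEG]
        a6 = kdeg * deg_pairs
        a7 = kcrawl * G[G_PLI]
        a8 = kunb * G[G_PLI]
        atot = a1i + a1n + a2 + a3 + a4 + a5 + a6 + a7 + a8
        if atot <= 0.0:
            # nothing can ever fire again (only possible with zeroed rates)
            integ_plg += G[G_PLG] * (t_max - t)
            t = t_max
            censored = tpa_present
            break
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / atot
        if t + dt >= t_max:
            integ_plg += G[G_PLG] * (t_max - t)
            t = t_max
            censored = tpa_present
            break
        integ_plg += G[G_PLG] * dt
        t += dt
        n_events += 1
        r_sel = np.random.random() * atot
        ev_loc = -1
        ev_d = -1
        ev_code = 0

        if r_sel < a1i + a1n:
            # --- PLG binding ---
            ev_code = 1
            if r_sel < a1i:
                col = ELI
                gidx = G_ELI
                want = 0
            else:
                col = ELN
                gidx = G_ELN
                want = 1
            j = int(np.random.random() * G[gidx])
            if j >= G[gidx]:
                j = G[gidx] - 1
            loc = 0
            while j >= C[loc, col]:
                j -= C[loc, col]
                loc += 1
            d = 0
            while True:
                if d >= 6:
                    anomaly |= 1
                    d = 5
                    break
                if (
                    exposed[loc, d] == 1
                    and fstate[loc, d] == want
                    and plg[loc, d] == 0
                ):
                    if j == 0:
                        break
                    j -= 1
                d += 1
            plg[loc, d] = 1
            C[loc, PLGC] += 1
            G[G_PLG] += 1
            C[loc, col] -= 1
            G[gidx] -= 1
            ev_loc, ev_d = loc, d
        elif r_sel < a1i + a1n + a2:
            # --- PLG unbinding ---
            ev_code = 2
            j = int(np.random.random() * G[G_PLG])
            if j >= G[G_PLG]:
                j = G[G_PLG] - 1
            loc = 0
            while j >= C[loc, PLGC]:
                j -= C[loc, PLGC]
                loc += 1
            d = 0
            while True:
                if d >= 6:
                    anomaly |= 2
                    d = 5
                    break
                if plg[loc, d] == 1:
                    if j == 0:
                        break
                    j -= 1
                d += 1
            plg[loc, d] = 0
            C[loc, PLGC] -= 1
            G[G_PLG] -= 1
            if accessible[loc] == 1 and exposed[loc, d] == 1 and fstate[loc, d] < 2:
                if fstate[loc, d] == 0:
                    C[loc, ELI] += 1
                    G[G_ELI] += 1
                else:
                    C[loc, ELN] += 1
                    G[G_ELN] += 1
            ev_loc, ev_d = loc, d
        elif r_sel < a1i + a1n + a2 + a3:
            # --- tPA kinetic unbinding ---
            ev_code = 3
            tpa_present = False
            leave_t = t
            mode = MODE_KINETIC
            ev_loc, ev_d = tpa_loc, tpa_dbl
        elif r_sel < a1i + a1n + a2 + a3 + a4:
            # --- activation: a PLG at the tPA's location becomes PLi in place ---
            ev_code = 4
            loc = tpa_loc
            j = int(np.random.random() * C[loc, PLGC])
            if j >= C[loc, PLGC]:
                j = C[loc, PLGC] - 1
            d = 0
            while True:
                if d >= 6:
                    anomaly |= 4
                    d = 5
                    break
                if plg[loc, d] == 1:
                    if j == 0:
                        break
                    j -= 1
                d += 1
            plg[loc, d] = 0
            C[loc, PLGC] -= 1
            G[G_PLG] -= 1
            if accessible[loc] == 1 and exposed[loc, d] == 1 and fstate[loc, d] < 2:
                if fstate[loc, d] == 0:
                    C[loc, ELI] += 1
                    G[G_ELI] += 1
                else:
                    C[loc, ELN] += 1
                    G[G_ELN] += 1
            if pli[loc, d] == 0:
                pli[loc, d] = 1
                C[loc, PLIC] += 1
                G[G_PLI] += 1
                G[G_EXPO] += C[loc, CRY]
                G[G_DEG] += C[loc, NOND]
            else:
                # doublet already holds a plasmin: the fresh one binds nearby
                tl, td = _pick_crawl_target(
                    loc, n, exposed, fstate, pli, crawl_opens_cryptic
                )
                if tl >= 0:
                    if exposed[tl, td] == 0:
                        _expose_doublet(
                            tl, td, fstate, exposed, plg, accessible, loc_nicked, C, G
                        )
                    pli[tl, td] = 1
                    C[tl, PLIC] += 1
                    G[G_PLI] += 1
                    G[G_EXPO] += C[tl, CRY]
                    G[G_DEG] += C[tl, NOND]
            plasmin_created += 1
            ev_loc, ev_d = loc, d
        elif r_sel < a1i + a1n + a2 + a3 + a4 + a5:
            # --- cryptic doublet exposure ---
            ev_code = 5
            x = np.random.random() * G[G_EXPO]
            loc = -1
            for cand in range(L):
                w = C[cand, PLIC] * C[cand, CRY]
                if w > 0:
                    loc = cand
                    if x < w:
                        break
                    x -= w
            if loc < 0:
                anomaly |= 8
                loc = 0
            j = int(np.random.random() * C[loc, CRY])
            if j >= C[loc, CRY]:
                j = C[loc, CRY] - 1
            d = 0
            while True:
                if d >= 6:
                    anomaly |= 16
                    d = 5
                    break
                if exposed[loc, d] == 0 and fstate[loc, d] < 2:
                    if j == 0:
                        break
                    j -= 1
                d += 1
            _expose_doublet(loc, d, fstate, exposed, plg, accessible, loc_nicked, C, G)
            ev_loc, ev_d = loc, d
        elif r_sel < a1i + a1n + a2 + a3 + a4 + a5 + a6:
            # --- degradation of a doublet at a plasmin's location ---
            ev_code = 6
            x = np.random.random() * deg_pairs
            loc = -1
            for cand in range(L):
                if spare_own:
                    w = C[cand, PLIC] * (C[cand, NOND] - 1)
                else:
                    w = C[cand, PLIC] * C[cand, NOND]
                if w > 0:
                    loc = cand
                    if x < w:
                        break
                    x -= w
            if loc < 0:
                anomaly |= 32
                loc = 0
            skip_d = -1
            if spare_own:
                # the acting plasmin spares the doublet its limbs occupy
                j = int(np.random.random() * C[loc, PLIC])
                if j >= C[loc, PLIC]:
                    j = C[loc, PLIC] - 1
                d = 0
                while True:
                    if d >= 6:
                        anomaly |= 64
                        d = 5
                        break
                    if pli[loc, d] == 1:
                        if j == 0:
                            break
                        j -= 1
                    d += 1
                skip_d = d
            navail = C[loc, NOND] - 1 if spare_own else C[loc, NOND]
            j = int(np.random.random() * navail)
            if j >= navail:
                j = navail - 1
            d = 0
            while True:
                if d >= 6:
                    anomaly |= 128
                    d = 5
                    break
                if fstate[loc, d] < 2 and d != skip_d:
                    if j == 0:
                        break
                    j -= 1
                d += 1
            # release occupants, then mark degraded
            if plg[loc, d] == 1:
                plg[loc, d] = 0
                C[loc, PLGC] -= 1
                G[G_PLG] -= 1
            elif accessible[loc] == 1 and exposed[loc, d] == 1:
                if fstate[loc, d] == 0:
                    C[loc, ELI] -= 1
                    G[G_ELI] -= 1
                else:
                    C[loc, ELN] -= 1
                    G[G_ELN] -= 1
            displaced_pli = False
            if pli[loc, d] == 1:
                # detach; it will rebind a nearby doublet below if one exists
                pli[loc, d] = 0
                C[loc, PLIC] -= 1
                G[G_PLI] -= 1
                G[G_EXPO] -= C[loc, CRY]
                G[G_DEG] -= C[loc, NOND]
                displaced_pli = True
            if tpa_present and loc == tpa_loc and d == tpa_dbl:
                tpa_present = False
                leave_t = t
                mode = MODE_FORCED
            if exposed[loc, d] == 0:
                C[loc, CRY] -= 1
                G[G_EXPO] -= C[loc, PLIC]
            fstate[loc, d] = 2
            C[loc, NOND] -= 1
            G[G_DEG] -= C[loc, PLIC]
            if loc_nicked[loc] == 0:
                loc_nicked[loc] = 1
                _nick_location(loc, fstate, exposed, plg, accessible, C, G)
            if displaced_pli and relocate_displaced:
                tl, td = _pick_crawl_target(
                    loc, n, exposed, fstate, pli, crawl_opens_cryptic
                )
                if tl >= 0:
                    if exposed[tl, td] == 0:
                        _expose_doublet(
                            tl, td, fstate, exposed, plg, accessible, loc_nicked, C, G
                        )
                    pli[tl, td] = 1
                    C[tl, PLIC] += 1
                    G[G_PLI] += 1
                    G[G_EXPO] += C[tl, CRY]
                    G[G_DEG] += C[tl, NOND]
            ev_loc, ev_d = loc, d
            if fully_deg[loc] == 0 and 6 - C[loc, NOND] >= cut_threshold:
                fully_deg[loc] = 1
                n_fully += 1
                rr = loc // n
                cc = loc % n
                if rr > 0:
                    _make_accessible(loc - n, fstate, exposed, plg, accessible, C, G)
                if rr < n - 1:
                    _make_accessible(loc + n, fstate, exposed, plg, accessible, C, G)
                if cc > 0:
                    _make_accessible(loc - 1, fstate, exposed, plg, accessible, C, G)
                if cc < n - 1:
                    _make_accessible(loc + 1, fstate, exposed, plg, accessible, C, G)
                if not lysed:
                    if require_full_grid:
                        if n_fully == L:
                            lysed = True
                    elif _transected(fully_deg, n, stack, seen):
                        lysed = True
                    if lysed:
                        lysis_t = t
                        if stop_at_lysis:
                            if tpa_present:
                                # the severed piece carries the tPA away
                                tpa_present = False
                                leave_t = t
                                mode = MODE_SEVERED
                            checksum = (
                                checksum * 131 + 6 * 7 + loc * 13 + d
                            ) % 2147483647
                            break
        elif r_sel < a1i + a1n + a2 + a3 + a4 + a5 + a6 + a7:
            # --- plasmin crawl to a 4-neighbor (or same-location) doublet ---
            ev_code = 7
            j = int(np.random.random() * G[G_PLI])
            if j >= G[G_PLI]:
                j = G[G_PLI] - 1
            loc = 0
            while j >= C[loc, PLIC]:
                j -= C[loc, PLIC]
                loc += 1
            d = 0
            while True:
                if d >= 6:
                    anomaly |= 256
                    d = 5
                    break
                if pli[loc, d] == 1:
                    if j == 0:
                        break
                    j -= 1
                d += 1
            tl, td = _pick_crawl_target(loc, n, exposed, fstate, pli, crawl_opens_cryptic)
            if tl >= 0:
                pli[loc, d] = 0
                C[loc, PLIC] -= 1
                G[G_EXPO] -= C[loc, CRY]
                G[G_DEG] -= C[loc, NOND]
                if exposed[tl, td] == 0:
                    _expose_doublet(
                        tl, td, fstate, exposed, plg, accessible, loc_nicked, C, G
                    )
                pli[tl, td] = 1
                C[tl, PLIC] += 1
                G[G_EXPO] += C[tl, CRY]
                G[G_DEG] += C[tl, NOND]
                ev_loc, ev_d = tl, td
            else:
                ev_loc, ev_d = loc, d  # no eligible target: no-op
        else:
            # --- plasmin kinetic unbinding (instant alpha2-AP inhibition) ---
            ev_code = 8
            j = int(np.random.random() * G[G_PLI])
            if j >= G[G_PLI]:
                j = G[G_PLI] - 1
            loc = 0
            while j >= C[loc, PLIC]:
                j -= C[loc, PLIC]
                loc += 1
            d = 0
            while True:
                if d >= 6:
                    anomaly |= 512
                    d = 5
                    break
                if pli[loc, d] == 1:
                    if j == 0:
                        break
                    j -= 1
                d += 1
            pli[loc, d] = 0
            C[loc, PLIC] -= 1
            G[G_PLI] -= 1
            G[G_EXPO] -= C[loc, CRY]
            G[G_DEG] -= C[loc, NOND]
            ev_loc, ev_d = loc, d

        checksum = (checksum * 131 + ev_code * 7 + ev_loc * 13 + ev_d) % 2147483647

    # cross-check incremental counters against a full recount
    ok = 1.0
    for loc in range(L):
        nplg = 0
        npli = 0
        ncry = 0
        nnond = 0
        eli = 0
        eln = 0
        for d in range(6):
            if plg[loc, d] == 1:
                nplg += 1
            if pli[loc, d] == 1:
                npli += 1
            if fstate[loc, d] < 2:
                nnond += 1
                if exposed[loc, d] == 0:
                    ncry += 1
                elif accessible[loc] == 1 and plg[loc, d] == 0:
                    if fstate[loc, d] == 0:
                        eli += 1
                    else:
                        eln += 1
        if (
            nplg != C[loc, PLGC]
            or npli != C[loc, PLIC]
            or ncry != C[loc, CRY]
            or nnond != C[loc, NOND]
            or eli != C[loc, ELI]
            or eln != C[loc, ELN]
        ):
            ok = 0.0

    out[RES_LEAVE_T] = leave_t
    out[RES_MODE] = mode
    out[RES_PLI_CREATED] = plasmin_created
    out[RES_LYSED] = 1.0 if lysed else 0.0
    out[RES_LYSIS_T] = lysis_t
    out[RES_CENSORED] = 1.0 if censored else 0.0
    out[RES_NEVENTS] = n_events
    out[RES_TEND] = t
    out[RES_PLG_INTEG] = integ_plg
    g_eli = 0
    g_eln = 0
    g_plg = 0
    g_pli = 0
    g_expo = 0
    g_deg = 0
    for loc in range(L):
        g_eli += C[loc, ELI]
        g_eln += C[loc, ELN]
        g_plg += C[loc, PLGC]
        g_pli += C[loc, PLIC]
        g_expo += C[loc, PLIC] * C[loc, CRY]
        g_deg += C[loc, PLIC] * C[loc, NOND]
    if (
        g_eli != G[G_ELI]
        or g_eln != G[G_ELN]
        or g_plg != G[G_PLG]
        or g_pli != G[G_PLI]
        or g_expo != G[G_EXPO]
        or g_deg != G[G_DEG]
    ):
        ok = 0.0
    if anomaly > 0:
        ok = -float(anomaly)
    out[RES_OK] = ok
    out[RES_CHECK] = float(checksum)
    out[RES_SEED] = float(seed)


@njit
def micro_ensemble_kernel(
    n,
    rates,
    n_runs,
    base_seed,
    t_max,
    require_full_grid,
    spare_own,
    cut_threshold,
    relocate_displaced,
    crawl_opens_cryptic,
    stop_at_lysis,
    exposed,
    fstate,
    plg,
    pli,
    accessible,
    loc_nicked,
    fully_deg,
    C,
    G,
    stack,
    seen,
    perim,
    out,
    res,
):
    """Independent seeded runs; per-run seed = (base_seed + 9973*i) mod (2^31-1)."""
    for i in range(n_runs):
        seed = (base_seed + 9973 * i) % 2147483647
        micro_ssa(
            n,
            rates,
            seed,
            t_max,
            require_full_grid,
            spare_own,
            cut_threshold,
            relocate_displaced,
            crawl_opens_cryptic,
            stop_at_lysis,
            exposed,
            fstate,
            plg,
            pli,
            accessible,
            loc_nicked,
            fully_deg,
            C,
            G,
            stack,
            seen,
            perim,
            out,
        )
        for j in range(N_RES):
            res[i, j] = out[j]


def make_workspace(n):
    """Caller-owned scratch arrays for the kernels (reused across runs)."""
    L = n * n
    return dict(
        exposed=np.zeros((L, 6), dtype=np.uint8),
        fstate=np.zeros((L, 6), dtype=np.uint8),
        plg=np.zeros((L, 6), dtype=np.uint8),
        pli=np.zeros((L, 6), dtype=np.uint8),
        accessible=np.zeros(L, dtype=np.uint8),
        loc_nicked=np.zeros(L, dtype=np.uint8),
        fully_deg=np.zeros(L, dtype=np.uint8),
        C=np.zeros((L, 6), dtype=np.int64),
        G=np.zeros(6, dtype=np.int64),
        stack=np.empty(L, dtype=np.int64),
        seen=np.empty(L, dtype=np.uint8),
        perim=np.empty(max(4 * n - 4, 1), dtype=np.int64),
        out=np.zeros(N_RES, dtype=np.float64),
    )
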
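"""Independently coded straight-line scalar reference for the weekly engine.

Pure-Python loops and ifs over one cell's 52-week series; no numpy
vectorization and no imports from the package under test.  Used to check
run_cell/run_grid for numerical equivalence.
"""


def trapezoid(x, x0, x1, x2, x3):
    if x <= x0 or x >= x3:
        return 0.0
    if x1 <= x <= x2:
        return 1.0
    if x < x1:
        return (x - x0) / (x1 - x0)
    return (x3 - x) / (x3 - x2)


def oracle_run_cell(
    tmin, tmax, rain, rh09, rh15, daylength, p,
    capacity=100.0, k_e=0.8, s_init=0.5, s_max=1.0,
):
    """Annual result dict for one cell; inputs are 52-element sequences."""
    n = 52
    tavg = [(tmin[w] + tmax[w]) / 2.0 for w in range(n)]
    evap = [
        k_e * 7.0 * max(0.0, tavg[w]) * max(0.0, 1.0 - (rh09[w] + rh15[w]) / 200.0)
        for w in range(n)
    ]

    # soil bucket iterated to a periodic steady state
    S = [0.0] * n
    state = s_init
    prev = None
    for _ in range(20):
        for w in range(n):
            state = state + (rain[w] - evap[w]) / capacity
            state = min(s_max, max(0.0, state))
            S[w] = state
        if prev is not None and max(abs(S[w] - prev[w]) for w in range(n)) < 1e-9:
            break
        prev = list(S)

    # winter diapause state machine, second cycle reported
    DI = [1.0] * n
    diap = False
    days_in = 0.0
    for cycle in range(2):
        for w in range(n):
            trend = daylength[(w + 1) % n] - daylength[w]
            if diap and trend > 0 and tavg[w] > p.DPT1 and days_in >= p.DPD:
                diap = False
                days_in = 0.0
            if (not diap) and trend < 0 and daylength[w] < p.DPD0 and tavg[w] < p.DPT0:
                diap = True
            if diap:
                days_in += 7.0
            if cycle == 1:
                DI[w] = 0.0 if diap else 1.0

    GI = [
        trapezoid(tavg[w], p.DV0, p.DV1, p.DV2, p.DV3)
        * trapezoid(S[w], p.SM0, p.SM1, p.SM2, p.SM3)
        * DI[w]
        for w in range(n)
    ]
    GI_A = 100.0 * sum(GI) / n

    CS = min(100.0, 100.0 * abs(p.THCS) * sum(max(0.0, p.TTCS - tmin[w]) for w in range(n)))
    HS = min(100.0, 100.0 * p.THHS * sum(max(0.0, tmax[w] - p.TTHS) for w in range(n)))
    DS = min(100.0, 100.0 * abs(p.HDS) * sum(max(0.0, p.SMDS - S[w]) for w in range(n)))
    WS = min(100.0, 100.0 * p.HWS * sum(max(0.0, S[w] - p.SMWS) for w in range(n)))
    HW = min(
        100.0,
        100.0 * p.PHW * sum(
            max(0.0, tavg[w] - p.TTHW) for w in range(n) if S[w] > p.MTHW
        ),
    )

    DD = 7.0 * sum(max(0.0, tavg[w] - p.DV0) for w in range(n))
    SI = (1 - CS / 100) * (1 - HS / 100) * (1 - DS / 100) * (1 - WS / 100) * (1 - HW / 100)
    EI = GI_A * SI
    if DD < p.PDD:
        EI = 0.0
    EI = min(100.0, max(0.0, EI))

    active = [w + 1 for w in range(n) if GI[w] > 0.0]
    return {
        "GI_A": GI_A, "CS": CS, "HS": HS, "DS": DS, "WS": WS, "HW": HW,
        "SI": SI, "DD_annual": DD, "generations": DD / p.PDD,
        "growth_weeks": len(active),
        "first_growth_week": active[0] if active else 0,
        "last_growth_week": active[-1] if active else 0,
        "EI": EI,
    }
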
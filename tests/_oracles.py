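"""Independent brute-force oracles used by the feature tests.

These re-derive the spectrum-over-threshold areas without the package's
slab integration: a vectorized np.select re-implementation of the
piecewise threshold curves, a 2-D (log-frequency x dB) cell-counting
integrator, and a Monte Carlo estimate of the total area.
"""

import numpy as np

from vibrotact.thresholds import RECEPTORS


def vector_thresholds(model, f):
    """Evaluate every receptor's piecewise curve on an array of frequencies."""
    f = np.asarray(f, float)
    out = {}
    for r, segs in model.segments.items():
        conds, vals = [], []
        for i, s in enumerate(segs):
            lo_ok = (
                f >= s.f_lo
                if (i == 0 and r not in model.domain_lo_exclusive)
                else f > s.f_lo
            )
            conds.append(lo_ok & (f <= s.f_hi))
            vals.append(s.slope * np.log10(np.maximum(f, 1e-300)) + s.intercept)
        out[r] = np.select(conds, vals, default=np.nan)
    return out


def _code_label(code):
    members = [r for b, r in enumerate(RECEPTORS) if code >> b & 1]
    return "ALL" if len(members) == len(RECEPTORS) else "".join(members)


def grid_oracle(freqs, db, model, f_range=(0.5, 800.0), n_sub=4, db_step=0.1):
    """Cell-counting area per firing combination on a fine 2-D grid."""
    freqs = np.asarray(freqs, float)
    db = np.asarray(db, float)
    dfreq = freqs[1] - freqs[0]
    lo = np.clip(freqs - dfreq / 2, *f_range)
    hi = np.clip(freqs + dfreq / 2, *f_range)
    keep = hi > lo
    f_sub, w_sub, s_sub = [], [], []
    for l, h, s in zip(np.log10(lo[keep]), np.log10(hi[keep]), db[keep]):
        edges = np.linspace(l, h, n_sub + 1)
        f_sub.append(10 ** ((edges[:-1] + edges[1:]) / 2))
        w_sub.append(np.diff(edges))
        s_sub.append(np.full(n_sub, s))
    f_sub = np.concatenate(f_sub)
    w_sub = np.concatenate(w_sub)
    s_sub = np.concatenate(s_sub)
    T = vector_thresholds(model, f_sub)
    Tm = np.vstack([T[r] for r in RECEPTORS])
    L0 = np.nanmin(Tm, axis=0)
    levels = np.arange(np.nanmin(L0), s_sub.max() + db_step, db_step) + db_step / 2
    D = {}
    for c in levels:
        active = (c > L0) & (c < s_sub)
        if not active.any():
            continue
        with np.errstate(invalid="ignore"):
            firing = Tm[:, active] <= c
        codes = (firing * (1 << np.arange(len(RECEPTORS)))[:, None]).sum(axis=0)
        area = w_sub[active] * db_step
        for code in np.unique(codes):
            if code == 0:
                continue
            label = _code_label(int(code))
            D[label] = D.get(label, 0.0) + float(area[codes == code].sum())
    return D


def monte_carlo_total_area(
    freqs, db, model, f_range=(0.5, 800.0), n_points=100_000, seed=0
):
    """Monte Carlo estimate of the total area above the lowest threshold."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, float)
    db = np.asarray(db, float)
    inside = (freqs >= f_range[0]) & (freqs <= f_range[1])
    u_lo, u_hi = np.log10(f_range[0]), np.log10(f_range[1])
    probe = vector_thresholds(model, np.geomspace(*f_range, 2048))
    floor = float(np.nanmin(np.vstack(list(probe.values()))))
    ceil = float(db[inside].max())
    if ceil <= floor:
        return 0.0
    u = rng.uniform(u_lo, u_hi, n_points)
    level = rng.uniform(floor, ceil, n_points)
    f = 10.0**u
    T = vector_thresholds(model, f)
    L0 = np.nanmin(np.vstack([T[r] for r in RECEPTORS]), axis=0)
    # spectrum level at the nearest bin (bins are a uniform grid)
    dfreq = freqs[1] - freqs[0]
    s = db[np.clip(np.rint(f / dfreq).astype(int), 0, len(db) - 1)]
    hit = (level > L0) & (level < s)
    box = (u_hi - u_lo) * (ceil - floor)
    return box * hit.mean()
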
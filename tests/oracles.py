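"""Independent brute-force implementations used as oracles.

Everything here is written as plain, explicit loops over blocks, epochs and
candidate predictors — deliberately naive, sharing no code path with the
package implementations it cross-checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_nonwear_mask(axis_means: np.ndarray, axis_sds: np.ndarray,
                       block_min: int = 15, window_min: int = 60,
                       sd_thr_mg: float = 13.0, mean_thr_mg: float = 50.0,
                       malfunction_g: float = 5.5) -> np.ndarray:
    """Explicit per-block nonwear rule on (n, 3) epoch-level stats."""
    n = axis_means.shape[0]
    epb = block_min * 4
    half = (window_min - block_min) * 4 // 2
    mask = np.zeros(n, dtype=bool)
    b = 0
    while b * epb < n:
        b0 = b * epb
        b1 = min(b0 + epb, n)
        w0 = max(0, b0 - half)
        w1 = min(n, b1 + half)
        low_sd = 0
        low_mean = 0
        for axis in range(3):
            mean_vals = [axis_means[i, axis] for i in range(w0, w1)]
            sd_vals = [axis_sds[i, axis] for i in range(w0, w1)]
            mu = sum(mean_vals) / len(mean_vals)
            within = sum(v * v for v in sd_vals) / len(sd_vals)
            between = sum((v - mu) ** 2 for v in mean_vals) / len(mean_vals)
            pooled_sd = math.sqrt(within + between)
            if pooled_sd < sd_thr_mg / 1000.0:
                low_sd += 1
            if abs(mu) < mean_thr_mg / 1000.0:
                low_mean += 1
        malfunction = all(
            max(abs(axis_means[i, 0]), abs(axis_means[i, 1]),
                abs(axis_means[i, 2])) > malfunction_g
            for i in range(b0, b1)
        )
        if low_sd >= 2 or low_mean >= 2 or malfunction:
            for i in range(b0, b1):
                mask[i] = True
        b += 1
    return mask


def naive_day_metrics(counts: np.ndarray, steps_by_minute: np.ndarray,
                      usable: np.ndarray) -> dict:
    """Per-epoch loop version of the daily metric computation.

    ``counts`` and ``usable`` are per 15-s epoch over one day (length 5760);
    ``steps_by_minute`` has length 1440 (NaN where absent).
    """
    sed = light = mod = vig = 0
    total = 0.0
    n_used = 0
    for i in range(len(counts)):
        if not usable[i]:
            continue
        n_used += 1
        c = counts[i]
        total += c
        if c <= 25:
            sed += 1
        elif c < 574:
            light += 1
        elif c < 1003:
            mod += 1
        else:
            vig += 1
    minute_vals = []
    for m in range(1440):
        if all(usable[4 * m + j] for j in range(4)) and not math.isnan(
                steps_by_minute[m]):
            minute_vals.append(steps_by_minute[m])
    bands = {"tzc_min": 0, "band_1_19": 0, "band_20_39": 0, "band_40_59": 0,
             "band_60_79": 0, "band_80_99": 0, "band_100_119": 0,
             "band_120_plus": 0}
    for v in minute_vals:
        if v == 0:
            bands["tzc_min"] += 1
        elif v < 20:
            bands["band_1_19"] += 1
        elif v < 40:
            bands["band_20_39"] += 1
        elif v < 60:
            bands["band_40_59"] += 1
        elif v < 80:
            bands["band_60_79"] += 1
        elif v < 100:
            bands["band_80_99"] += 1
        elif v < 120:
            bands["band_100_119"] += 1
        else:
            bands["band_120_plus"] += 1
    out = {
        "sedentary_min": sed / 4, "light_min": light / 4,
        "moderate_min": mod / 4, "vigorous_min": vig / 4,
        "mean_counts15": total / n_used if n_used else float("nan"),
        "steps": float(sum(minute_vals)),
        "n_step_minutes": len(minute_vals),
    }
    out.update(bands)
    for n in (1, 30, 60):
        ordered = sorted(minute_vals, reverse=True)[:n]
        out[f"peak{n}"] = (sum(ordered) / len(ordered)) if ordered else float("nan")
    return out


def _r2(y: np.ndarray, X_cols: list[np.ndarray]) -> float:
    X = np.column_stack([np.ones(len(y))] + X_cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid ** 2).sum() / sst


def naive_stepwise(table, outcome: str, pool: list[str],
                   alpha: float = 0.05, vif_limit: float = 7.0) -> list[str]:
    """Exhaustive forward selection with the same add/VIF rules."""
    from scipy.stats import f as fdist

    y = table[outcome].to_numpy(float)
    n = len(y)
    selected: list[str] = []
    banned: list[str] = []
    while True:
        cands = [p for p in pool if p not in selected and p not in banned]
        if not cands:
            break
        best = None
        best_r2 = -1.0
        for cand in cands:
            r2 = _r2(y, [table[c].to_numpy(float) for c in selected + [cand]])
            if r2 > best_r2 + 1e-12:
                best, best_r2 = cand, r2
        base_r2 = _r2(y, [table[c].to_numpy(float) for c in selected]) \
            if selected else 0.0
        k = len(selected) + 1
        df2 = n - k - 1
        F = (best_r2 - base_r2) / max(1e-300, (1 - best_r2) / df2)
        p = 1.0 - fdist.cdf(F, 1, df2)
        if p >= alpha:
            break
        selected.append(best)
        while len(selected) >= 2:
            vifs = []
            for j, pred in enumerate(selected):
                others = [table[q].to_numpy(float)
                          for q in selected if q != pred]
                r2j = _r2(table[pred].to_numpy(float), others)
                vifs.append(1.0 / max(1e-12, 1.0 - r2j))
            if max(vifs) <= vif_limit:
                break
            worst = int(np.argmax(vifs))
            banned.append(selected.pop(worst))
    return selected
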
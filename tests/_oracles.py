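"""Independent brute-force oracles used to verify the vectorised engine.

Everything here is written as explicit per-voxel Python loops, sharing no
code path with the package implementation it checks.
"""

import numpy as np


def oracle_labels(z, threshold):
    """Per-voxel threshold-then-argmax labelling, ties to lowest index."""
    k = z.shape[0]
    labels = np.full(z.shape[1:], np.nan)
    for idx in np.ndindex(z.shape[1:]):
        best, best_z = None, None
        for i in range(k):
            zi = z[(i, *idx)]
            if zi > threshold and (best_z is None or zi > best_z):
                best, best_z = i + 1, zi
        if best is not None:
            labels[idx] = best
    return labels


def oracle_metrics(values, binary, sizes, bounds=None):
    """Per-voxel accumulation of every engagement metric.

    ``values``: the (possibly thresholded) statistic volume, NaN/0 inactive.
    ``binary``: (K, *shape) 0/1 masks; ``sizes``: |ICN_i| denominators.
    Returns (per_icn dict of length-K arrays, global dict).
    """
    k = binary.shape[0]
    inter = np.zeros(k)
    sums = np.zeros(k)
    n_active = 0
    vmin, vmax = np.inf, -np.inf
    for idx in np.ndindex(values.shape):
        v = values[idx]
        if np.isfinite(v) and v != 0:
            n_active += 1
            vmin = min(vmin, v)
            vmax = max(vmax, v)
            for i in range(k):
                if binary[(i, *idx)]:
                    inter[i] += 1
                    sums[i] += v
    if bounds is not None:
        vmin, vmax = bounds
    nums = np.zeros(k)
    if n_active and vmax > vmin:
        for idx in np.ndindex(values.shape):
            v = values[idx]
            if np.isfinite(v) and v != 0:
                u = min(max((v - vmin) / (vmax - vmin), 0.0), 1.0)
                for i in range(k):
                    if binary[(i, *idx)]:
                        nums[i] += u

    per = {}
    per["I"] = inter / sizes
    tot = inter.sum()
    per["IR"] = inter / tot if tot > 0 else np.full(k, np.nan)
    per["OL"] = inter / n_active if n_active > 0 else np.full(k, np.nan)
    per["SQ"] = 2 * inter / (n_active + sizes)
    per["J"] = inter / (n_active + sizes - inter)
    per["MA"] = np.array(
        [sums[i] / inter[i] if inter[i] > 0 else np.nan for i in range(k)]
    )
    per["MA_N"] = np.array(
        [nums[i] / inter[i] if inter[i] > 0 else np.nan for i in range(k)]
    )
    tot_num = nums.sum()
    per["RA_N"] = nums / tot_num if tot_num > 0 else np.full(k, np.nan)
    per["I_M"] = nums / sizes
    man = per["MA_N"]
    s = np.nansum(man) if np.isfinite(man).any() else np.nan
    per["IR_M"] = man / s if s and s > 0 else np.full(k, np.nan)

    tot_c = inter.sum()
    glob = {
        "I_T": tot / sizes.sum(),
        "MA": sums.sum() / tot_c if tot_c > 0 else np.nan,
        "MA_N": tot_num / tot_c if tot_c > 0 else np.nan,
        "I_T_M": tot_num / sizes.sum(),
    }
    return per, glob


def oracle_icc_consistency(x):
    """Textbook two-way ANOVA consistency ICC, scalar loops only."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ms_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
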
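"""Independent brute-force reference implementations used as test oracles.

Everything here is written in the most literal way possible — explicit
loops, no vectorization, no reuse of package internals — so agreement with
the pipeline is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def psth_zscore_reference(trial_spikes, epoch_length, bin_s=0.010,
                          sigma_s=0.030, baseline=(0.0, 0.5)):
    """Literal binning + discrete-Gaussian-convolution + z-score.

    Mirrors the documented conventions: 10 ms bins, sampled Gaussian kernel
    truncated at ±4σ and renormalized, reflection at the edges, z against
    the baseline bins (bin center < baseline end) with population SD.
    """
    n_bins = int(round(epoch_length / bin_s))
    counts = [0.0] * n_bins
    for spikes in trial_spikes:
        for t in spikes:
            b = int(t / bin_s)
            if 0 <= b < n_bins:
                counts[b] += 1.0
    rate = [c / (len(trial_spikes) * bin_s) for c in counts]

    sigma_bins = sigma_s / bin_s
    radius = int(4.0 * sigma_bins + 0.5)
    kernel = [math.exp(-0.5 * (k / sigma_bins) ** 2)
              for k in range(-radius, radius + 1)]
    ksum = sum(kernel)
    kernel = [k / ksum for k in kernel]

    def reflected(i):
        # scipy 'reflect' convention: (d c b a | a b c d | d c b a)
        n = n_bins
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return rate[i]

    smoothed = []
    for i in range(n_bins):
        acc = 0.0
        for k in range(-radius, radius + 1):
            acc += kernel[k + radius] * reflected(i - k)
        smoothed.append(acc)

    base = [smoothed[i] for i in range(n_bins)
            if baseline[0] <= (i + 0.5) * bin_s < baseline[1]]
    mu = sum(base) / len(base)
    var = sum((x - mu) ** 2 for x in base) / len(base)
    sd = math.sqrt(var)
    if sd == 0.0:
        return None
    return np.array([(x - mu) / sd for x in smoothed])


def detect_peaks_reference(z, t, min_height=0.1, min_sep=0.100,
                           window=None):
    """Exhaustive O(n²) peak detection under the height/separation rules.

    Strict local maxima inside the window with height >= min_height,
    accepted in order of decreasing height (earlier first on ties), each
    checked against *every* previously accepted peak.
    """
    n = len(z)
    if window is None:
        window = (0.5, t[-1] + 1.0)
    candidates = []
    for i in range(1, n - 1):
        if z[i] > z[i - 1] and z[i] > z[i + 1]:
            if window[0] <= t[i] <= window[1] and z[i] >= min_height:
                candidates.append(i)
    candidates.sort(key=lambda i: (-z[i], t[i]))
    accepted = []
    for i in candidates:
        ok = True
        for j in accepted:
            if abs(t[i] - t[j]) < min_sep:
                ok = False
        if ok:
            accepted.append(i)
    accepted.sort()
    return np.array([t[i] for i in accepted])


def ks_statistic_reference(a, b):
    """sup |ECDF_a − ECDF_b| by evaluating both ECDFs at every breakpoint."""
    a, b = list(a), list(b)
    best = 0.0
    for x in a + b:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


def signed_rank_reference(x, y):
    """Wilcoxon signed-rank W (smaller of the two signed-rank sums) and the
    exact two-sided p by enumerating all 2^n sign assignments.

    Zero differences dropped; mean ranks for tied |d|.
    """
    d = [xi - yi for xi, yi in zip(x, y) if xi != yi]
    n = len(d)
    absd = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and absd[j][0] == absd[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = avg
        i = j
    w_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    w_minus = sum(r for r, v in zip(ranks, d) if v < 0)
    w = min(w_plus, w_minus)
    # exact null distribution of W+ over all sign assignments
    total = 2 ** n
    cnt_le = cnt_ge = 0
    for mask in range(total):
        s = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if s <= w_plus + 1e-12:
            cnt_le += 1
        if s >= w_plus - 1e-12:
            cnt_ge += 1
    p = min(1.0, 2.0 * min(cnt_le, cnt_ge) / total)
    return w, p


def chamber_entries_reference(membership, chamber_idx):
    """Entries = count of frames where membership switches into the chamber."""
    entries = 0
    for i in range(1, len(membership)):
        if membership[i] == chamber_idx and membership[i - 1] != chamber_idx:
            entries += 1
    return entries


def dsi_reference(responses, directions, preferred):
    """Literal (Rpref − Rortho)/(Rpref + Rortho), orthogonal = mean of the
    two directions at ±90°, responses floored at zero."""
    r = {d % 360: max(v, 0.0) for d, v in zip(directions, responses)}
    rp = r[preferred % 360]
    ro = (r[(preferred + 90) % 360] + r[(preferred - 90) % 360]) / 2.0
    if rp + ro == 0:
        return float("nan")
    return (rp - ro) / (rp + ro)
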
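"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain Python loops over voxels / matrix
entries, deliberately sharing no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def all_offsets(ndim, unique=True):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=ndim):
        if all(v == 0 for v in d):
            continue
        if unique and tuple(-v for v in d) in offs:
            continue
        offs.append(d)
    return offs


def in_bounds(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


# ---------------------------------------------------------------------------
# matrices by exhaustive enumeration
# ---------------------------------------------------------------------------

def glcm_oracle(levels, ng, off):
    P = np.zeros((ng, ng))
    for p in itertools.product(*[range(n) for n in levels.shape]):
        a = levels[p]
        if a == 0:
            continue
        q = tuple(c + d for c, d in zip(p, off))
        if not in_bounds(q, levels.shape):
            continue
        b = levels[q]
        if b == 0:
            continue
        P[a - 1, b - 1] += 1
        P[b - 1, a - 1] += 1  # symmetrization
    return P


def glrlm_oracle(levels, ng, off):
    """Run-length matrix by scanning every maximal run."""
    runs = []
    for p in itertools.product(*[range(n) for n in levels.shape]):
        v = levels[p]
        if v == 0:
            continue
        prev = tuple(c - d for c, d in zip(p, off))
        if in_bounds(prev, levels.shape) and levels[prev] == v:
            continue  # not a run start
        length = 1
        cur = tuple(c + d for c, d in zip(p, off))
        while in_bounds(cur, levels.shape) and levels[cur] == v:
            length += 1
            cur = tuple(c + d for c, d in zip(cur, off))
        runs.append((v, length))
    max_len = max((l for _, l in runs), default=1)
    R = np.zeros((ng, max_len))
    for v, l in runs:
        R[v - 1, l - 1] += 1
    return R


def glszm_zones_oracle(levels):
    """Flood-fill zone list [(level, size), ...], full connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    nb = all_offsets(levels.ndim, unique=False)
    zones = []
    for p in itertools.product(*[range(n) for n in shape]):
        if levels[p] == 0 or seen[p]:
            continue
        v = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for off in nb:
                r = tuple(c + d for c, d in zip(q, off))
                if in_bounds(r, shape) and not seen[r] and levels[r] == v:
                    seen[r] = True
                    stack.append(r)
        zones.append((int(v), size))
    return zones


def glszm_oracle(levels, ng):
    zones = glszm_zones_oracle(levels)
    max_size = max((s for _, s in zones), default=1)
    S = np.zeros((ng, max_size))
    for v, s in zones:
        S[v - 1, s - 1] += 1
    return S


def gldm_oracle(levels, ng, alpha=0):
    nb = all_offsets(levels.ndim, unique=False)
    entries = []
    for p in itertools.product(*[range(n) for n in levels.shape]):
        v = levels[p]
        if v == 0:
            continue
        dep = 0
        for off in nb:
            q = tuple(c + d for c, d in zip(p, off))
            if in_bounds(q, levels.shape) and levels[q] > 0 and abs(int(levels[q]) - int(v)) <= alpha:
                dep += 1
        entries.append((int(v), dep))
    max_dep = max((d for _, d in entries), default=0)
    D = np.zeros((ng, max_dep + 1))
    for v, d in entries:
        D[v - 1, d] += 1
    return D


def ngtdm_oracle(levels, ng):
    nb = all_offsets(levels.ndim, unique=False)
    n = np.zeros(ng)
    s = np.zeros(ng)
    for p in itertools.product(*[range(m) for m in levels.shape]):
        v = levels[p]
        if v == 0:
            continue
        vals = []
        for off in nb:
            q = tuple(c + d for c, d in zip(p, off))
            if in_bounds(q, levels.shape) and levels[q] > 0:
                vals.append(int(levels[q]))
        if not vals:
            continue
        n[v - 1] += 1
        s[v - 1] += abs(int(v) - sum(vals) / len(vals))
    return n, s


# ---------------------------------------------------------------------------
# feature formulas by explicit loops (from the enumerated matrices)
# ---------------------------------------------------------------------------

def glcm_features_oracle(P):
    """Loop-based GLCM descriptors from a symmetrized count matrix."""
    ng = P.shape[0]
    tot = P.sum()
    p = P / tot
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] += p[i][j]
            psum[i + j] += p[i][j]
    da = sum(k * pdiff[k] for k in range(ng))
    out = {}
    out["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    out["JointAverage"] = mu
    for nm, expo in (("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)):
        out[nm] = sum((i + 1 + j + 1 - 2 * mu) ** expo * p[i][j]
                      for i in range(ng) for j in range(ng))
    out["Contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    out["Correlation"] = (out["Autocorrelation"] - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(v * math.log2(v) for v in pdiff if v > 0)
    out["DifferenceVariance"] = sum((k - da) ** 2 * pdiff[k] for k in range(ng))
    out["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0)
    out["JointEntropy"] = hxy
    out["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    out["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    out["Idmn"] = sum(p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng))
    out["Idn"] = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    out["InverseVariance"] = sum(p[i][j] / (i - j) ** 2
                                 for i in range(ng) for j in range(ng) if i != j)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hxy1 = -sum(p[i][j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if p[i][j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if px[i] * px[j] > 0)
    out["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    out["SumAverage"] = sum((k + 2) * psum[k] for k in range(2 * ng - 1))
    out["SumEntropy"] = -sum(v * math.log2(v) for v in psum if v > 0)
    out["SumSquares"] = sigma2
    # MCC via the Q-matrix second eigenvalue
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) < 2:
        out["MCC"] = 1.0
    else:
        Q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a, b] = sum(p[i][k] * p[j][k] / (px[i] * px[k]) for k in keep)
        ev = sorted(np.linalg.eigvals(Q).real)
        out["MCC"] = math.sqrt(max(0.0, ev[-2]))
    return out


def size_matrix_features_oracle(M, n_voxels, names):
    """Loop-based level x size matrix descriptors (GLRLM/GLSZM shape).

    ``names`` maps the 16 canonical roles to family feature names in the
    order: small, large, gln, glnn, sn, snn, perc, glvar, svar, entropy,
    lgl, hgl, slgl, shgl, llgl, lhgl.
    """
    ng, ns = M.shape
    N = M.sum()
    out = {}
    out[names[0]] = sum(M[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / N
    out[names[1]] = sum(M[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(ns)) / N
    out[names[2]] = sum(sum(M[i]) ** 2 for i in range(ng)) / N
    out[names[3]] = sum(sum(M[i]) ** 2 for i in range(ng)) / N ** 2
    colsums = [sum(M[i][j] for i in range(ng)) for j in range(ns)]
    out[names[4]] = sum(c ** 2 for c in colsums) / N
    out[names[5]] = sum(c ** 2 for c in colsums) / N ** 2
    out[names[6]] = N / n_voxels
    mu_i = sum((i + 1) * M[i][j] for i in range(ng) for j in range(ns)) / N
    mu_j = sum((j + 1) * M[i][j] for i in range(ng) for j in range(ns)) / N
    out[names[7]] = sum((i + 1 - mu_i) ** 2 * M[i][j] for i in range(ng) for j in range(ns)) / N
    out[names[8]] = sum((j + 1 - mu_j) ** 2 * M[i][j] for i in range(ng) for j in range(ns)) / N
    out[names[9]] = -sum((M[i][j] / N) * math.log2(M[i][j] / N)
                         for i in range(ng) for j in range(ns) if M[i][j] > 0)
    out[names[10]] = sum(M[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)) / N
    out[names[11]] = sum(M[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(ns)) / N
    out[names[12]] = sum(M[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
                         for i in range(ng) for j in range(ns)) / N
    out[names[13]] = sum(M[i][j] * (i + 1) ** 2 / (j + 1) ** 2
                         for i in range(ng) for j in range(ns)) / N
    out[names[14]] = sum(M[i][j] * (j + 1) ** 2 / (i + 1) ** 2
                         for i in range(ng) for j in range(ns)) / N
    out[names[15]] = sum(M[i][j] * (i + 1) ** 2 * (j + 1) ** 2
                         for i in range(ng) for j in range(ns)) / N
    return out


GLRLM_ROLE_ORDER = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM_ROLE_ORDER = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]


def gldm_features_oracle(D):
    ng, nd = D.shape
    N = D.sum()
    out = {}
    out["SmallDependenceEmphasis"] = sum(D[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    out["LargeDependenceEmphasis"] = sum(D[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    out["GrayLevelNonUniformity"] = sum(sum(D[i]) ** 2 for i in range(ng)) / N
    colsums = [sum(D[i][j] for i in range(ng)) for j in range(nd)]
    out["DependenceNonUniformity"] = sum(c ** 2 for c in colsums) / N
    out["DependenceNonUniformityNormalized"] = sum(c ** 2 for c in colsums) / N ** 2
    mu_i = sum((i + 1) * D[i][j] for i in range(ng) for j in range(nd)) / N
    mu_j = sum((j + 1) * D[i][j] for i in range(ng) for j in range(nd)) / N
    out["GrayLevelVariance"] = sum((i + 1 - mu_i) ** 2 * D[i][j] for i in range(ng) for j in range(nd)) / N
    out["DependenceVariance"] = sum((j + 1 - mu_j) ** 2 * D[i][j] for i in range(ng) for j in range(nd)) / N
    out["DependenceEntropy"] = -sum((D[i][j] / N) * math.log2(D[i][j] / N)
                                    for i in range(ng) for j in range(nd) if D[i][j] > 0)
    out["LowGrayLevelEmphasis"] = sum(D[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    out["HighGrayLevelEmphasis"] = sum(D[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    out["SmallDependenceLowGrayLevelEmphasis"] = sum(
        D[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nd)) / N
    out["SmallDependenceHighGrayLevelEmphasis"] = sum(
        D[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    out["LargeDependenceLowGrayLevelEmphasis"] = sum(
        D[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    out["LargeDependenceHighGrayLevelEmphasis"] = sum(
        D[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    return out


def ngtdm_features_oracle(n, s):
    ng = len(n)
    Nv = sum(n)
    p = [ni / Nv for ni in n]
    act = [i for i in range(ng) if p[i] > 0]
    out = {}
    ps = sum(p[i] * s[i] for i in act)
    out["Coarseness"] = 1.0 / ps if ps > 0 else 1e6
    if len(act) > 1:
        out["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in act for j in act)
            / (len(act) * (len(act) - 1))
        ) * (sum(s) / Nv)
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in act for j in act)
        out["Busyness"] = ps / denom if denom > 0 else 0.0
        out["Complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in act for j in act
        ) / Nv
        ssum = sum(s)
        out["Strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in act for j in act) / ssum
            if ssum > 0 else 0.0
        )
    else:
        out.update({"Contrast": 0.0, "Busyness": 0.0, "Complexity": 0.0, "Strength": 0.0})
    return out


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def icc2_anova_oracle(x):
    """ICC(2,1) from explicit sum-of-squares loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    row = [sum(x[i]) / k for i in range(n)]
    col = [sum(x[:, j]) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def welch_oracle(a, b):
    """Welch t statistic, dof and two-sided p from the closed form."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), dof)
    return t, dof, p


def auc_concordant_pairs(y, scores):
    """AUC as the fraction of concordant (positive, negative) score pairs,
    ties counting one half."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def threshold_scan_oracle(scores, y):
    """Exhaustive balanced-accuracy scan over midpoints of sorted unique
    scores (plus a below-minimum candidate); lowest maximizer wins."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    uniq = sorted(set(s))
    cands = [uniq[0] - 1.0] + [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    best_t, best_ba = None, -1.0
    for t in cands:
        pred = (s >= t).astype(int)
        sens = ((pred == 1) & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = ((pred == 0) & (y == 0)).sum() / max((y == 0).sum(), 1)
        ba = (sens + spec) / 2
        if ba > best_ba + 1e-12:
            best_ba, best_t = ba, t
    return best_t


def collinearity_prune_oracle(table, r_threshold=0.8):
    """Step-by-step independent re-execution of the pruning rule."""
    import pandas as pd

    cols = [c for c in table.columns if table[c].std() > 0]
    while True:
        sub = table[cols]
        corr = sub.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        max_r = corr.values.max()
        if max_r <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = cols[i], cols[j]
        mean_a = corr.iloc[i].sum() / (len(cols) - 1)
        mean_b = corr.iloc[j].sum() / (len(cols) - 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        cols = [c for c in cols if c != drop]
    return cols
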
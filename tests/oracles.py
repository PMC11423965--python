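"""Naive brute-force texture-feature oracles.

Everything here is written as plain Python loops over explicit pair/run/
zone/neighbourhood enumerations, with no shared code or vectorized paths
from the package, so it can serve as an independent check of the matrix
feature implementations on small patches.
"""

from __future__ import annotations

import math
from collections import Counter

EPS = 2.220446049250313e-16  # np.spacing(1)


# ---------------------------------------------------------------- GLCM


def glcm_counts(levels, dy, dx):
    """Symmetric co-occurrence counts for one offset, by direct enumeration."""
    h, w = len(levels), len(levels[0])
    counts = Counter()
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                counts[(levels[y][x], levels[y2][x2])] += 1
                counts[(levels[y2][x2], levels[y][x])] += 1
    return counts


def glcm_features_naive(levels, ng):
    """Angle-averaged GLCM features; offsets match 0/45/90/135 degrees."""
    per_angle = []
    for dy, dx in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
        counts = glcm_counts(levels, dy, dx)
        total = sum(counts.values())
        p = {ij: c / total for ij, c in counts.items()}
        per_angle.append(_glcm_one(p, ng))
    return {k: sum(d[k] for d in per_angle) / 4.0 for k in per_angle[0]}


def _glcm_one(p, ng):
    px = [0.0] * (ng + 1)
    py = [0.0] * (ng + 1)
    for (i, j), v in p.items():
        px[i] += v
        py[j] += v
    mu_x = sum(i * px[i] for i in range(1, ng + 1))
    mu_y = sum(j * py[j] for j in range(1, ng + 1))
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(1, ng + 1)))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(1, ng + 1)))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for (i, j), v in p.items():
        p_diff[abs(i - j)] += v
        p_sum[i + j - 2] += v

    autocorr = sum(i * j * v for (i, j), v in p.items())
    joint_ent = -sum(v * math.log2(v + EPS) for v in p.values())
    hx = -sum(q * math.log2(q + EPS) for q in px[1:])
    hy = -sum(q * math.log2(q + EPS) for q in py[1:])
    hxy1 = -sum(v * math.log2(px[i] * py[j] + EPS) for (i, j), v in p.items())
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + EPS)
        for i in range(1, ng + 1)
        for j in range(1, ng + 1)
    )
    if sig_x > 0 and sig_y > 0:
        corr = (autocorr - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 1.0
    imc1 = (joint_ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - joint_ent))))
    diff_avg = sum(k * v for k, v in enumerate(p_diff))

    occupied = [i for i in range(1, ng + 1) if px[i] > 0]
    if len(occupied) > 1:
        import numpy as _np

        q = _np.zeros((len(occupied), len(occupied)))
        for a, i in enumerate(occupied):
            for b, j in enumerate(occupied):
                q[a, b] = sum(
                    p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
                    for k in occupied
                )
        eig = sorted(_np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": sum(
            (i + j - mu_x - mu_y) ** 4 * v for (i, j), v in p.items()
        ),
        "ClusterShade": sum((i + j - mu_x - mu_y) ** 3 * v for (i, j), v in p.items()),
        "ClusterTendency": sum(
            (i + j - mu_x - mu_y) ** 2 * v for (i, j), v in p.items()
        ),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": -sum(v * math.log2(v + EPS) for v in p_diff),
        "DifferenceVariance": sum(
            (k - diff_avg) ** 2 * v for k, v in enumerate(p_diff)
        ),
        "Id": sum(v / (1.0 + abs(i - j)) for (i, j), v in p.items()),
        "Idm": sum(v / (1.0 + (i - j) ** 2) for (i, j), v in p.items()),
        "Idmn": sum(v / (1.0 + ((i - j) / ng) ** 2) for (i, j), v in p.items()),
        "Idn": sum(v / (1.0 + abs(i - j) / ng) for (i, j), v in p.items()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(
            v / (i - j) ** 2 for (i, j), v in p.items() if i != j
        ),
        "JointAverage": mu_x,
        "JointEnergy": sum(v**2 for v in p.values()),
        "JointEntropy": joint_ent,
        "MaximumProbability": max(p.values()),
        "MCC": mcc,
        "SumAverage": sum((k + 2) * v for k, v in enumerate(p_sum)),
        "SumEntropy": -sum(v * math.log2(v + EPS) for v in p_sum),
        "SumSquares": sum((i - mu_x) ** 2 * v for (i, j), v in p.items()),
    }


# ---------------------------------------------------------------- GLRLM


def runs_in_line(line):
    runs = []
    start = 0
    for k in range(1, len(line) + 1):
        if k == len(line) or line[k] != line[start]:
            runs.append((line[start], k - start))
            start = k
    return runs


def all_runs(levels, direction):
    h, w = len(levels), len(levels[0])
    lines = []
    if direction == "0":
        lines = [list(row) for row in levels]
    elif direction == "90":
        lines = [[levels[y][x] for y in range(h)] for x in range(w)]
    elif direction == "45":
        for s in range(h + w - 1):  # x + y = s, walking up-right
            lines.append(
                [levels[y][s - y] for y in range(h - 1, -1, -1) if 0 <= s - y < w]
            )
    elif direction == "135":
        for d in range(-(h - 1), w):  # x - y = d, walking down-right
            lines.append([levels[y][y + d] for y in range(h) if 0 <= y + d < w])
    out = []
    for line in lines:
        out.extend(runs_in_line(line))
    return out


def glrlm_features_naive(levels, ng):
    n_pix = len(levels) * len(levels[0])
    per_dir = []
    for direction in ("0", "45", "90", "135"):
        counts = Counter(all_runs(levels, direction))
        per_dir.append(_rlm_szm_features(counts, n_pix, prefix="run"))
    return {k: sum(d[k] for d in per_dir) / 4.0 for k in per_dir[0]}


def _rlm_szm_features(counts, n_pix, prefix):
    """Shared run-length / size-zone feature arithmetic on (level, size) counts."""
    n = sum(counts.values())
    pg = Counter()
    ps = Counter()
    for (i, s), c in counts.items():
        pg[i] += c
        ps[s] += c
    mu_i = sum(i * c for (i, _), c in counts.items()) / n
    mu_s = sum(s * c for (_, s), c in counts.items()) / n
    feats = {
        "small": sum(c / s**2 for (_, s), c in counts.items()) / n,
        "large": sum(c * s**2 for (_, s), c in counts.items()) / n,
        "gln": sum(c**2 for c in pg.values()) / n,
        "glnn": sum(c**2 for c in pg.values()) / n**2,
        "sn": sum(c**2 for c in ps.values()) / n,
        "snn": sum(c**2 for c in ps.values()) / n**2,
        "pct": n / n_pix,
        "glv": sum((i - mu_i) ** 2 * c for (i, _), c in counts.items()) / n,
        "sv": sum((s - mu_s) ** 2 * c for (_, s), c in counts.items()) / n,
        "ent": -sum((c / n) * math.log2(c / n + EPS) for c in counts.values()),
        "lgl": sum(c / i**2 for (i, _), c in counts.items()) / n,
        "hgl": sum(c * i**2 for (i, _), c in counts.items()) / n,
        "slgl": sum(c / (i**2 * s**2) for (i, s), c in counts.items()) / n,
        "shgl": sum(c * i**2 / s**2 for (i, s), c in counts.items()) / n,
        "llgl": sum(c * s**2 / i**2 for (i, s), c in counts.items()) / n,
        "lhgl": sum(c * i**2 * s**2 for (i, s), c in counts.items()) / n,
    }
    return feats


GLRLM_KEYMAP = {
    "ShortRunEmphasis": "small",
    "LongRunEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "sn",
    "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "pct",
    "GrayLevelVariance": "glv",
    "RunVariance": "sv",
    "RunEntropy": "ent",
    "LowGrayLevelRunEmphasis": "lgl",
    "HighGrayLevelRunEmphasis": "hgl",
    "ShortRunLowGrayLevelEmphasis": "slgl",
    "ShortRunHighGrayLevelEmphasis": "shgl",
    "LongRunLowGrayLevelEmphasis": "llgl",
    "LongRunHighGrayLevelEmphasis": "lhgl",
}

GLSZM_KEYMAP = {
    "SmallAreaEmphasis": "small",
    "LargeAreaEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "sn",
    "SizeZoneNonUniformityNormalized": "snn",
    "ZonePercentage": "pct",
    "GrayLevelVariance": "glv",
    "ZoneVariance": "sv",
    "ZoneEntropy": "ent",
    "LowGrayLevelZoneEmphasis": "lgl",
    "HighGrayLevelZoneEmphasis": "hgl",
    "SmallAreaLowGrayLevelEmphasis": "slgl",
    "SmallAreaHighGrayLevelEmphasis": "shgl",
    "LargeAreaLowGrayLevelEmphasis": "llgl",
    "LargeAreaHighGrayLevelEmphasis": "lhgl",
}


# ---------------------------------------------------------------- GLSZM


def zones(levels):
    """8-connected same-level zones by breadth-first flood fill."""
    h, w = len(levels), len(levels[0])
    seen = [[False] * w for _ in range(h)]
    out = []
    for y0 in range(h):
        for x0 in range(w):
            if seen[y0][x0]:
                continue
            lvl = levels[y0][x0]
            stack = [(y0, x0)]
            seen[y0][x0] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        y2, x2 = y + dy, x + dx
                        if (
                            0 <= y2 < h
                            and 0 <= x2 < w
                            and not seen[y2][x2]
                            and levels[y2][x2] == lvl
                        ):
                            seen[y2][x2] = True
                            stack.append((y2, x2))
            out.append((lvl, size))
    return out


def glszm_features_naive(levels, ng):
    n_pix = len(levels) * len(levels[0])
    counts = Counter(zones(levels))
    return _rlm_szm_features(counts, n_pix, prefix="zone")


# ---------------------------------------------------------------- NGTDM


def ngtdm_features_naive(levels, ng):
    h, w = len(levels), len(levels[0])
    n_pix = h * w
    n_i = [0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    for y in range(h):
        for x in range(w):
            nbrs = [
                levels[y + dy][x + dx]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0) and 0 <= y + dy < h and 0 <= x + dx < w
            ]
            lvl = levels[y][x]
            n_i[lvl] += 1
            s_i[lvl] += abs(lvl - sum(nbrs) / len(nbrs))
    present = [i for i in range(1, ng + 1) if n_i[i] > 0]
    p = {i: n_i[i] / n_pix for i in present}
    ngp = len(present)
    denom = sum(p[i] * s_i[i] for i in present)
    coarseness = min(1.0 / denom if denom > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * sum(s_i[i] for i in present)
            / n_pix
        )
        denom_busy = sum(
            abs(i * p[i] - j * p[j]) for i in present for j in present
        )
        busyness = denom / denom_busy if denom_busy > 0 else 0.0
        complexity = (
            sum(
                abs(i - j)
                * (p[i] * s_i[i] + p[j] * s_i[j])
                / (p[i] + p[j])
                for i in present
                for j in present
            )
            / n_pix
        )
        denom_str = sum(s_i[i] for i in present)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
            / denom_str
            if denom_str > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------- GLDM


def gldm_features_naive(levels, ng, alpha=0):
    h, w = len(levels), len(levels[0])
    counts = Counter()
    for y in range(h):
        for x in range(w):
            dep = 1  # the centre pixel
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy, dx) == (0, 0):
                        continue
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < h and 0 <= x2 < w:
                        if abs(levels[y][x] - levels[y2][x2]) <= alpha:
                            dep += 1
            counts[(levels[y][x], dep)] += 1
    n = sum(counts.values())
    pg = Counter()
    pd = Counter()
    for (i, d), c in counts.items():
        pg[i] += c
        pd[d] += c
    mu_i = sum(i * c for (i, _), c in counts.items()) / n
    mu_d = sum(d * c for (_, d), c in counts.items()) / n
    return {
        "SmallDependenceEmphasis": sum(c / d**2 for (_, d), c in counts.items()) / n,
        "LargeDependenceEmphasis": sum(c * d**2 for (_, d), c in counts.items()) / n,
        "GrayLevelNonUniformity": sum(c**2 for c in pg.values()) / n,
        "DependenceNonUniformity": sum(c**2 for c in pd.values()) / n,
        "DependenceNonUniformityNormalized": sum(c**2 for c in pd.values()) / n**2,
        "GrayLevelVariance": sum((i - mu_i) ** 2 * c for (i, _), c in counts.items())
        / n,
        "DependenceVariance": sum((d - mu_d) ** 2 * c for (_, d), c in counts.items())
        / n,
        "DependenceEntropy": -sum(
            (c / n) * math.log2(c / n + EPS) for c in counts.values()
        ),
        "LowGrayLevelEmphasis": sum(c / i**2 for (i, _), c in counts.items()) / n,
        "HighGrayLevelEmphasis": sum(c * i**2 for (i, _), c in counts.items()) / n,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            c / (i**2 * d**2) for (i, d), c in counts.items()
        )
        / n,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            c * i**2 / d**2 for (i, d), c in counts.items()
        )
        / n,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            c * d**2 / i**2 for (i, d), c in counts.items()
        )
        / n,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            c * i**2 * d**2 for (i, d), c in counts.items()
        )
        / n,
    }
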
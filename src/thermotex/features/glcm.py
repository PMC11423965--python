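"""Gray Level Co-occurrence Matrix features.

The co-occurrence matrices themselves come from
``skimage.feature.graycomatrix`` (distance 1; angles 0, 45, 90, 135 degrees;
symmetric).  The 24 features are computed from each angle's normalized
matrix and averaged over the four angles, so the angle-averaged values are
invariant under 90-degree patch rotation.

Degenerate conventions (documented so constant patches stay finite):
Correlation and MCC are 1 when the patch has a single occupied gray level;
IMC1/IMC2 are 0 when the marginal entropies vanish.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

from .quantize import QuantizedPatch

_EPS = np.spacing(1.0)

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "MCC",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


_GRID_CACHE: dict[int, tuple] = {}


def _grids(ng: int):
    if ng not in _GRID_CACHE:
        i = np.arange(1, ng + 1, dtype=np.float64)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        _GRID_CACHE[ng] = (i, ii, jj, np.abs(ii - jj).astype(np.int64))
    return _GRID_CACHE[ng]


def _single_angle(p: np.ndarray, ng: int) -> dict[str, float]:
    i, ii, jj, absdiff = _grids(ng)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # diagonal (difference) and cross-diagonal (sum) marginal distributions
    k_diff = np.arange(ng, dtype=np.float64)  # |i-j| = 0..Ng-1
    p_diff = np.zeros(ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)  # i+j = 2..2Ng
    p_sum = np.zeros(2 * ng - 1)
    sums = (ii + jj).astype(np.int64)
    np.add.at(p_diff, absdiff.ravel(), p.ravel())
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())

    autocorr = float(np.sum(ii * jj * p))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    joint_ent = float(-np.sum(p * np.log2(p + _EPS)))
    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))

    if sig_x > 0 and sig_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0
    if max(hx, hy) > 0:
        imc1 = (joint_ent - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_ent)))))

    # MCC: sqrt of the second-largest eigenvalue of Q, restricted to
    # occupied gray levels so the division is well defined.
    occ = px > 0
    if occ.sum() > 1:
        p_occ = p[np.ix_(occ, occ)]
        # Q_uv = sum_k p(u,k) p(v,k) / (px(u) py(k))
        q = np.einsum("uk,vk->uv", p_occ / px[occ][:, None], p_occ / py[occ][None, :])
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    diff_avg = float(np.sum(k_diff * p_diff))
    off = absdiff > 0
    cp_base = ii + jj - mu_x - mu_y
    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(np.sum(cp_base**4 * p)),
        "ClusterShade": float(np.sum(cp_base**3 * p)),
        "ClusterTendency": float(np.sum(cp_base**2 * p)),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p[off] / (ii - jj)[off] ** 2)),
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": joint_ent,
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
    }


def glcm_features(q: QuantizedPatch, distance: int = 1) -> dict[str, float]:
    """24 GLCM features at the given offset distance, averaged over 4 angles."""
    mats = graycomatrix(
        (q.levels - 1).astype(np.uint8),
        distances=[distance],
        angles=list(ANGLES),
        levels=q.n_levels,
        symmetric=True,
    ).astype(np.float64)
    out = {name: 0.0 for name in GLCM_NAMES}
    for a in range(mats.shape[3]):
        m = mats[:, :, 0, a]
        total = m.sum()
        feats = _single_angle(m / total if total > 0 else m, q.n_levels)
        for name in GLCM_NAMES:
            out[name] += feats[name]
    return {name: v / len(ANGLES) for name, v in out.items()}
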
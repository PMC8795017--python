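"""Gray-level texture matrices and their scalar features.

All five classic 3D texture encodings are built from a
:class:`~otoradiomics.preprocess.DiscretizedROI` (integer gray levels 1..Ng,
0 outside the ROI):

* GLCM  — co-occurrence of gray-level pairs at Chebyshev distance 1, one
  symmetric matrix per each of the 13 unique 3D directions, features averaged
  over directions (26 features);
* GLRLM — run lengths of equal gray level along the 13 directions, features
  averaged over directions (16 features);
* GLSZM — sizes of 26-connected equal-gray-level zones (16 features);
* GLDM  — gray-level dependence: for each voxel the number of equal-valued
  neighbors in its 26-neighborhood (7 features);
* NGTDM — neighborhood gray-tone difference (5 features).

Degenerate single-level ROIs take documented limit values (entropies 0,
energies 1, NGTDM coarseness capped at 1e6) rather than erroring: perfectly
flat wavelet sub-bands do occur for constant ROIs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrices",
    "glcm_features",
    "glrlm_matrices",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
]

_EPS = np.spacing(1.0)
_COARSENESS_CAP = 1e6


def _unique_directions() -> list[tuple[int, int, int]]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d > (0, 0, 0):  # lexicographically positive half
                    dirs.append(d)
    return dirs


#: the 13 unique (up to sign) offsets at Chebyshev distance 1 in 3D
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(_unique_directions())


def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Paired views (a, b) such that b is a shifted by offset d."""
    src, dst = [], []
    for n, step in zip(arr.shape, d):
        if step == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        elif step == -1:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
        else:
            src.append(slice(None))
            dst.append(slice(None))
    return arr[tuple(src)], arr[tuple(dst)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrices(disc: DiscretizedROI) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrices, shape (13, Ng, Ng)."""
    lab = disc.labels
    ng = disc.n_levels
    out = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=np.float64)
    for k, d in enumerate(DIRECTIONS_13):
        a, b = _shifted_views(lab, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        av = a[valid] - 1
        bv = b[valid] - 1
        counts = np.bincount(av * ng + bv, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
        sym = counts + counts.T
        out[k] = sym / sym.sum()
    return out


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu = float((ii * p).sum())  # joint average; px == py by symmetry
    sig2 = float(((i - mu) ** 2 * px).sum())

    # difference distribution p_{|i-j|}
    kdiff = np.arange(ng, dtype=np.float64)
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).astype(int), p)
    diff_avg = float((kdiff * pdiff).sum())

    # sum distribution p_{i+j}, k = 2..2Ng
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    psum = np.zeros(2 * ng - 1)
    np.add.at(psum, (ii + jj).astype(int) - 2, p)

    joint_entropy = float(-(p * np.log2(p + _EPS)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    absdiff = np.abs(ii - jj)
    off = absdiff > 0
    inv_var = float((p[off] / absdiff[off] ** 2).sum()) if off.any() else 0.0

    if ng > 1 and px.min() > 0:
        q = (p / px[:, None]) @ (p / py[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if ev.size > 1 else 1.0
    else:
        # includes Ng == 1 and matrices with empty marginal rows
        mcc = 1.0

    if sig2 > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / sig2)
    else:
        correlation = 1.0

    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": mu,
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "difference_average": diff_avg,
        "difference_entropy": float(-(pdiff * np.log2(pdiff + _EPS)).sum()),
        "difference_variance": float(((kdiff - diff_avg) ** 2 * pdiff).sum()),
        "dissimilarity": float((absdiff * p).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": joint_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "id": float((p / (1.0 + absdiff)).sum()),
        "idn": float((p / (1.0 + absdiff / ng)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "mcc": mcc,
        "sum_average": float((ksum * psum).sum()),
        "sum_entropy": float(-(psum * np.log2(psum + _EPS)).sum()),
        "sum_squares": sig2,
        "sum_variance": float(((ksum - (ksum * psum).sum()) ** 2 * psum).sum()),
    }


GLCM_FEATURE_NAMES = tuple(
    _glcm_features_single(np.ones((1, 1))).keys()
)  # 26 names, fixed order


def glcm_features(disc: DiscretizedROI) -> dict[str, float]:
    """26 co-occurrence features averaged over the 13 directions."""
    mats = glcm_matrices(disc)
    acc: dict[str, float] = {k: 0.0 for k in GLCM_FEATURE_NAMES}
    n_used = 0
    for p in mats:
        if p.sum() == 0:
            continue
        n_used += 1
        for k, v in _glcm_features_single(p).items():
            acc[k] += v
    if n_used == 0:
        # single isolated voxel: no co-occurring pairs in any direction
        return dict.fromkeys(GLCM_FEATURE_NAMES, 0.0)
    return {k: v / n_used for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrices(disc: DiscretizedROI) -> list[np.ndarray]:
    """Run-length matrices P(gray level, run length), one per direction.

    Runs are maximal sequences of ROI voxels with equal gray level along a
    lattice line; out-of-ROI voxels break runs.  For every direction the
    length-weighted total equals the ROI voxel count.
    """
    lab = disc.labels
    ng = disc.n_levels
    coords = np.argwhere(lab > 0)
    vals = lab[lab > 0]
    mats = []
    if coords.size == 0:
        return [np.zeros((ng, 1)) for _ in DIRECTIONS_13]
    for d in DIRECTIONS_13:
        dv = np.array(d)
        axis = int(np.nonzero(dv)[0][0])
        t = coords[:, axis] * dv[axis]  # unit step index along the direction
        line = coords - t[:, None] * dv[None, :]
        order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
        ts = t[order]
        ls = line[order]
        vs = vals[order]
        same_line = np.all(ls[1:] == ls[:-1], axis=1)
        contiguous = ts[1:] == ts[:-1] + 1
        same_val = vs[1:] == vs[:-1]
        cont = same_line & contiguous & same_val
        starts = np.flatnonzero(np.concatenate(([True], ~cont)))
        ends = np.concatenate((starts[1:], [vs.size]))
        lengths = ends - starts
        levels = vs[starts]
        max_len = int(lengths.max())
        mat = np.zeros((ng, max_len), dtype=np.float64)
        np.add.at(mat, (levels - 1, lengths - 1), 1.0)
        mats.append(mat)
    return mats


def _rlm_szm_features(mat: np.ndarray, n_vox: int, prefix: str) -> dict[str, float]:
    """Shared feature formulas for run-length and size-zone matrices.

    ``prefix`` selects the naming: run (SRE/LRE/...) or zone (SAE/LAE/...).
    """
    ntot = mat.sum()
    if ntot == 0:
        mat = np.zeros((1, 1))
        mat[0, 0] = 1.0
        ntot = 1.0
    ng, nl = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    p = mat / ntot
    ri = mat.sum(axis=1)
    rj = mat.sum(axis=0)
    mu_i = float((i[:, 0] * ri / ntot).sum())
    mu_j = float((j[0, :] * rj / ntot).sum())

    run = prefix == "run"
    names = {
        "small": "SRE" if run else "SAE",
        "large": "LRE" if run else "LAE",
        "gln": "GLN",
        "glnn": "GLNN",
        "ln": "RLN" if run else "SZN",
        "lnn": "RLNN" if run else "SZNN",
        "pct": "RP" if run else "ZP",
        "glv": "GLV",
        "lv": "RV" if run else "ZV",
        "ent": "RE" if run else "ZE",
        "lgl": "LGLRE" if run else "LGLZE",
        "hgl": "HGLRE" if run else "HGLZE",
        "sl": "SRLGLE" if run else "SALGLE",
        "sh": "SRHGLE" if run else "SAHGLE",
        "ll": "LRLGLE" if run else "LALGLE",
        "lh": "LRHGLE" if run else "LAHGLE",
    }
    return {
        names["small"]: float((mat / j**2).sum() / ntot),
        names["large"]: float((mat * j**2).sum() / ntot),
        names["gln"]: float((ri**2).sum() / ntot),
        names["glnn"]: float((ri**2).sum() / ntot**2),
        names["ln"]: float((rj**2).sum() / ntot),
        names["lnn"]: float((rj**2).sum() / ntot**2),
        names["pct"]: float(ntot / max(n_vox, 1)),
        names["glv"]: float((p * (i - mu_i) ** 2).sum()),
        names["lv"]: float((p * (j - mu_j) ** 2).sum()),
        names["ent"]: float(-(p * np.log2(p + _EPS)).sum()),
        names["lgl"]: float((mat / i**2).sum() / ntot),
        names["hgl"]: float((mat * i**2).sum() / ntot),
        names["sl"]: float((mat / (i**2 * j**2)).sum() / ntot),
        names["sh"]: float((mat * i**2 / j**2).sum() / ntot),
        names["ll"]: float((mat * j**2 / i**2).sum() / ntot),
        names["lh"]: float((mat * i**2 * j**2).sum() / ntot),
    }


GLRLM_FEATURE_NAMES = tuple(_rlm_szm_features(np.ones((1, 1)), 1, "run").keys())
GLSZM_FEATURE_NAMES = tuple(_rlm_szm_features(np.ones((1, 1)), 1, "zone").keys())


def glrlm_features(disc: DiscretizedROI) -> dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    n_vox = int((disc.labels > 0).sum())
    mats = glrlm_matrices(disc)
    acc = {k: 0.0 for k in GLRLM_FEATURE_NAMES}
    for mat in mats:
        for k, v in _rlm_szm_features(mat, n_vox, "run").items():
            acc[k] += v
    return {k: v / len(mats) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix P(gray level, zone size), 26-connected zones."""
    lab = disc.labels
    ng = disc.n_levels
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, ng + 1):
        binary = lab == g
        if not binary.any():
            continue
        comp, n_comp = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(comp.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


def glszm_features(disc: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (zones are 26-connected)."""
    n_vox = int((disc.labels > 0).sum())
    return _rlm_szm_features(glszm_matrix(disc), n_vox, "zone")


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Dependence matrix P(gray level, dependence size).

    The dependence size of a voxel is 1 (itself) plus the number of its 26
    neighbors inside the ROI with an identical gray level.
    """
    lab = disc.labels
    ng = disc.n_levels
    roi = lab > 0
    dep = np.zeros(lab.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _shifted_views(lab, d)
        eq = (a > 0) & (b > 0) & (a == b)
        sa, sb = _shifted_views(dep, d)
        sa += eq
        sb += eq
    sizes = dep[roi] + 1
    levels = lab[roi]
    mat = np.zeros((ng, int(sizes.max())), dtype=np.float64)
    np.add.at(mat, (levels - 1, sizes - 1), 1.0)
    return mat


def gldm_features(disc: DiscretizedROI) -> dict[str, float]:
    """7 gray-level dependence features."""
    mat = gldm_matrix(disc)
    ntot = mat.sum()
    ng, nd = mat.shape
    j = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    p = mat / ntot
    ri = mat.sum(axis=1)
    rj = mat.sum(axis=0)
    mu_j = float((j[0, :] * rj / ntot).sum())
    return {
        "SDE": float((mat / j**2).sum() / ntot),
        "LDE": float((mat * j**2).sum() / ntot),
        "GLN": float((ri**2).sum() / ntot),
        "DN": float((rj**2).sum() / ntot),
        "DNN": float((rj**2).sum() / ntot**2),
        "DV": float((p * (j - mu_j) ** 2).sum()),
        "DE": float(-(p * np.log2(p + _EPS)).sum()),
    }


GLDM_FEATURE_NAMES = ("SDE", "LDE", "GLN", "DN", "DNN", "DV", "DE")


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-gray-level (n_i, s_i) of the neighborhood gray-tone difference.

    s_i sums |i - A| over ROI voxels of level i, where A is the mean gray
    level of the voxel's in-ROI 26-neighbors; voxels without any in-ROI
    neighbor are excluded.  Returns (n, s, n_valid_voxels).
    """
    lab = disc.labels
    ng = disc.n_levels
    roi = (lab > 0).astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(lab.astype(np.float64) * roi, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(roi, kernel, mode="constant", cval=0.0)
    valid = (lab > 0) & (nb_cnt > 0)
    a = nb_sum[valid] / nb_cnt[valid]
    levels = lab[valid]
    n = np.bincount(levels - 1, minlength=ng).astype(np.float64)
    s = np.zeros(ng)
    np.add.at(s, levels - 1, np.abs(levels - a))
    return n, s, int(valid.sum())


def ngtdm_features(disc: DiscretizedROI) -> dict[str, float]:
    """5 neighborhood gray-tone difference features."""
    n, s, nvp = ngtdm_table(disc)
    if nvp == 0:
        return {"coarseness": _COARSENESS_CAP, "contrast": 0.0, "busyness": 0.0,
                "complexity": 0.0, "strength": 0.0}
    p = n / nvp
    i = np.arange(1, n.size + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s[present]

    denom = float((pp * sp).sum())
    coarseness = min(1.0 / denom, _COARSENESS_CAP) if denom > 0 else _COARSENESS_CAP

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * di**2).sum()) * s.sum() / (ngp * (ngp - 1) * nvp)
        bus_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = float((pp * sp).sum()) / bus_den if bus_den > 0 else 0.0
        num = np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
        complexity = float((num / (pp[:, None] + pp[None, :])).sum()) / nvp
        s_sum = s.sum()
        strength = (
            float(((pp[:, None] + pp[None, :]) * di**2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


NGTDM_FEATURE_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")
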
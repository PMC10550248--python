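"""Generalized Procrustes analysis, bilateral symmetry and allometry.

Landmark configurations are superimposed by iterative GPA: each
configuration is centred, scaled to unit centroid size, and rotated to
the running consensus with the proper orthogonal (det +1) solution;
the consensus is the coordinate-wise mean, re-normalised each round.
Reflections are excluded everywhere except in the deliberate mirroring
step of the object-symmetry decomposition, where each specimen's
mirror image (coordinates reflected through the midsagittal plane,
paired labels swapped) is superimposed together with the original.  The
symmetric component of a specimen is the mean of its aligned original
and mirror, the asymmetric component half their difference, so the two
components reconstruct the aligned coordinates exactly.

Centroid sizes are kept on the original measurement scale: the
"cranial size" analysed downstream is centroid size, not the aligned
(unit-size) coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import LandmarkConfiguration, PairingMap
from .permlm import PermLMResult, rrpp_lm

MIDLINE_TOL_FRAC = 0.05  # warn when midline points sit beyond 5% of CS off-plane


class AlignmentError(ValueError):
    """A configuration cannot be superimposed (degenerate geometry)."""


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    xyz = config.coordinates if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = xyz - xyz.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs == 0.0:
        raise ValueError("all landmarks coincident: centroid size is zero")
    return cs


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising ||a @ R - b||_F."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass
class AlignedShapeSet:
    """Procrustes-aligned configurations with size and symmetry channels."""

    specimen_ids: list[str]
    procrustes_coords: np.ndarray           # (n, k, 3), unit centroid size
    centroid_sizes: np.ndarray              # (n,), original units
    consensus: np.ndarray                   # (k, 3)
    symmetric_component: np.ndarray | None = None
    asymmetric_component: np.ndarray | None = None
    pairing: PairingMap | None = None
    iterations: int = 0
    final_change: float = float("nan")

    @property
    def n(self) -> int:
        return self.procrustes_coords.shape[0]

    @property
    def k(self) -> int:
        return self.procrustes_coords.shape[1]


def _center_scale(xyz: np.ndarray, specimen_id: str = "?") -> tuple[np.ndarray, float]:
    centred = xyz - xyz.mean(axis=0)
    if np.linalg.matrix_rank(centred) < 2:
        raise AlignmentError(f"{specimen_id}: configuration is degenerate (rank < 2)")
    cs = float(np.sqrt(np.sum(centred**2)))
    return centred / cs, cs


def _gpa_arrays(arrays: list[np.ndarray], ids: list[str],
                tol: float = 1e-10, max_iter: int = 200):
    """Core GPA loop on pre-validated raw coordinate arrays."""
    scaled, sizes = [], []
    for xyz, sid in zip(arrays, ids):
        z, cs = _center_scale(np.asarray(xyz, float), sid)
        scaled.append(z)
        sizes.append(cs)
    aligned = np.stack(scaled)
    consensus = aligned[0].copy()
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(aligned.shape[0]):
            aligned[i] = aligned[i] @ _rotation_to(aligned[i], consensus)
        new = aligned.mean(axis=0)
        new /= np.sqrt(np.sum(new**2))
        change = float(np.sqrt(np.sum((new - consensus) ** 2)))
        consensus = new
        if change < tol:
            break
    # report the plain coordinate-wise mean of the aligned configurations
    return aligned, np.asarray(sizes), aligned.mean(axis=0), it, change


def gpa(configs: list[LandmarkConfiguration], tol: float = 1e-10,
        max_iter: int = 200) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of >= 2 configurations."""
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"configurations disagree on landmark count: {sorted(ks)}")
    ids = [c.specimen_id for c in configs]
    aligned, sizes, consensus, it, change = _gpa_arrays(
        [c.coordinates for c in configs], ids, tol=tol, max_iter=max_iter
    )
    return AlignedShapeSet(
        specimen_ids=ids,
        procrustes_coords=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        pairing=configs[0].pairing,
        iterations=it,
        final_change=change,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared difference between two aligned shapes."""
    return float(np.sqrt(np.sum((a - b) ** 2)))


def mirror_config(xyz: np.ndarray, pairing: PairingMap) -> np.ndarray:
    """Reflect through the x=0 plane and swap paired landmark labels.

    Applying the operation twice returns the original array exactly.
    """
    reflected = xyz * np.array([-1.0, 1.0, 1.0])
    out = reflected.copy()
    for left, right in pairing.pairs:
        out[left] = reflected[right]
        out[right] = reflected[left]
    return out


def _check_midline_plane(xyz: np.ndarray, pairing: PairingMap, specimen_id: str) -> None:
    mid = np.asarray(pairing.midline, dtype=int)
    if mid.size < 4:
        return  # a plane through <= 3 points fits exactly
    pts = xyz[mid] - xyz[mid].mean(axis=0)
    normal = np.linalg.svd(pts)[2][-1]
    dist = np.abs(pts @ normal)
    tol = MIDLINE_TOL_FRAC * centroid_size(xyz)
    if np.any(dist > tol):
        warnings.warn(
            f"{specimen_id}: midline landmark(s) off the fitted midsagittal plane; "
            f"distances {np.round(dist, 4).tolist()} exceed tolerance {tol:.4g}",
            stacklevel=3,
        )


def bilateral_symmetry(configs: list[LandmarkConfiguration],
                       pairing: PairingMap | None = None) -> AlignedShapeSet:
    """Object-symmetry decomposition via joint GPA of originals + mirrors."""
    if pairing is None:
        pairing = configs[0].pairing
    if pairing is None:
        raise ValueError("bilateral_symmetry needs a pairing map")
    pairing.validate(configs[0].k)

    ids = [c.specimen_id for c in configs]
    for c in configs:
        _check_midline_plane(c.coordinates, pairing, c.specimen_id)
    originals = [c.coordinates for c in configs]
    mirrors = [mirror_config(x, pairing) for x in originals]
    aligned, sizes, consensus, it, change = _gpa_arrays(
        originals + mirrors, ids + [f"{s}__mirror" for s in ids]
    )
    n = len(configs)
    orig, mirr = aligned[:n], aligned[n:]
    symmetric = 0.5 * (orig + mirr)
    asymmetric = 0.5 * (orig - mirr)
    return AlignedShapeSet(
        specimen_ids=ids,
        procrustes_coords=orig,
        centroid_sizes=sizes[:n],
        consensus=consensus,
        symmetric_component=symmetric,
        asymmetric_component=asymmetric,
        pairing=pairing,
        iterations=it,
        final_change=change,
    )


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

def _join_shape_table(shapes: AlignedShapeSet, records: pd.DataFrame) -> pd.DataFrame:
    if len(set(shapes.specimen_ids)) != len(shapes.specimen_ids):
        raise ValueError("duplicate specimen ids in the aligned shape set")
    id_to_row = {sid: i for i, sid in enumerate(shapes.specimen_ids)}
    missing = [s for s in records["specimen_id"] if s not in id_to_row]
    if missing:
        raise ValueError(f"records without landmarks: {missing[:5]}")
    rows = [id_to_row[s] for s in records["specimen_id"]]
    out = records.copy().reset_index(drop=True)
    out["_shape_row"] = rows
    out["log_centroid_size"] = np.log(shapes.centroid_sizes[rows])
    return out


def allometry_model(
    shapes: AlignedShapeSet,
    records: pd.DataFrame,
    response: str = "shape",
    n_perm: int = 1000,
    seed: int = 0,
    use_symmetric: bool = True,
) -> PermLMResult:
    """Ontogenetic allometry: response ~ log(centroid size) * sex.

    ``response="shape"`` regresses the (multivariate) symmetric Procrustes
    coordinates on log centroid size, sex and their interaction;
    ``response="pes"`` runs the same engine on pes length.
    """
    joined = _join_shape_table(shapes, records)
    if response == "shape":
        block = shapes.symmetric_component if use_symmetric else shapes.procrustes_coords
        Y = block.reshape(shapes.n, -1)[joined["_shape_row"]]
    elif response == "pes":
        Y = joined["pes_length_cm"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}")
    data = joined[["log_centroid_size", "sex"]]
    result = rrpp_lm(
        Y, data, ["log_centroid_size", "sex", "log_centroid_size:sex"],
        n_perm=n_perm, seed=seed,
    )
    x = data["log_centroid_size"].to_numpy(dtype=float)
    size_beta, *_ = np.linalg.lstsq(
        np.column_stack([np.ones_like(x), x]), np.atleast_2d(Y.T).T, rcond=None
    )
    result.design_info.update(
        response=response,
        shape_k=shapes.k if response == "shape" else None,
        factor_levels={"sex": sorted(data["sex"].unique())},
        covariate_means={
            "log_centroid_size": float(x.mean()),
            "sex": float((data["sex"] == sorted(data["sex"].unique())[1]).mean()),
        },
        covariate_range=(float(x.min()), float(x.max())),
        size_coefficients=size_beta,
    )
    return result


def predicted_shape(fit: PermLMResult, at: dict) -> np.ndarray:
    """Shape predicted along the ontogenetic size axis.

    Uses the shape ~ log(centroid size) regression underlying the
    allometry model; ``at["log_centroid_size"]`` selects the point on
    the axis.  Evaluating at the covariate mean returns the sample mean
    shape exactly (the regression passes through the mean).
    Extrapolating log size beyond 1.2x the observed range warns.
    """
    info = fit.design_info
    if info.get("response") != "shape" or "size_coefficients" not in info:
        raise ValueError("predicted_shape needs a fitted multivariate allometry model")
    x = float(at["log_centroid_size"])

    lo, hi = info["covariate_range"]
    span = hi - lo
    mid = 0.5 * (lo + hi)
    # allowed interval = observed range inflated to 1.2x about its centre
    if span > 0 and abs(x - mid) > 0.6 * span:
        warnings.warn(f"log centroid size {x:.4g} extrapolates beyond 1.2x the observed range")
    flat = np.array([1.0, x]) @ info["size_coefficients"]
    return flat.reshape(info["shape_k"], 3)
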
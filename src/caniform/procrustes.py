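"""Generalized Procrustes superimposition with object symmetry.

The superimposition is *partial* Procrustes: every configuration is
centred and rescaled once to unit centroid size, then only translated and
rotated during the iterations.  Object (bilateral) symmetry is handled by
the reflect-and-relabel construction: each configuration enters the
superimposition together with its mirrored, label-swapped copy, and the
symmetric component of a specimen is the mean of its two aligned copies.
A two-effect Procrustes ANOVA (individuals vs digitization replicates,
Goodall's F) quantifies measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LandmarkConfiguration, SymmetryMap


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks to their centroid (mm)."""
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ValueError("expected a K x d coordinate matrix")
    centered = c - c.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def rigid_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``source`` onto ``target``.

    Returns ``(R, t, residual)`` with ``source @ R + t`` the fitted
    coordinates, ``R`` a proper rotation (det = +1; reflections are
    forbidden so anatomical sides can never be swapped silently) and
    ``residual`` the minimal summed squared distance.
    """
    a = np.asarray(source, dtype=float)
    b = np.asarray(target, dtype=float)
    if a.shape != b.shape:
        raise ValueError("source and target must have identical shape")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.allclose(a0, 0) or np.allclose(b0, 0):
        raise ValueError("degenerate configuration: all landmarks coincide")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(len(s))
    flip[-1] = d
    rot = (u * flip) @ vt
    fitted = a0 @ rot
    residual = float(np.sum((fitted - b0) ** 2))
    t = cb - ca @ rot
    return rot, t, residual


def opa_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Ordinary Procrustes fit (translation + proper rotation, no scaling)."""
    return rigid_fit(source, target)


def _center_unit(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered / np.sqrt(np.sum(centered**2))


def _reflect_relabel(coords: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Mirror across the x = 0 plane and swap left/right labels."""
    out = coords.copy()
    out[:, 0] = -out[:, 0]
    return out[perm]


def _axis_sign(v: np.ndarray) -> float:
    """Deterministic sign of an axis: third moment, falling back to the
    entry of largest magnitude."""
    s = float(np.sum(v**3))
    if abs(s) < 1e-12:
        s = float(v[np.argmax(np.abs(v))])
    return 1.0 if s >= 0 else -1.0


def _canonical_rotation(
    consensus: np.ndarray, left_rows: np.ndarray | None
) -> np.ndarray:
    """Gauge-fixing rotation: a GPA solution is only defined up to a global
    rotation, so the consensus is put in a canonical orientation (principal
    axes, deterministic signs).  With object symmetry only rotations that
    keep x as the symmetry axis are allowed: an in-plane (y, z) principal
    axis rotation plus half-turns fixing the y sign (third moment) and the
    x sign (left landmarks on positive x).
    """
    c = consensus - consensus.mean(axis=0)
    if left_rows is None:
        _, vecs = np.linalg.eigh(c.T @ c)
        rot = vecs[:, ::-1]  # descending variance
        if np.linalg.det(rot) < 0:
            rot[:, -1] = -rot[:, -1]
        signs = np.array([_axis_sign((c @ rot)[:, a]) for a in range(3)])
        if signs.prod() < 0:
            moments = [abs(np.sum((c @ rot)[:, a] ** 3)) for a in range(3)]
            signs[int(np.argmin(moments))] *= -1
        return rot * signs
    yz = c[:, 1:]
    _, vecs = np.linalg.eigh(yz.T @ yz)
    vy, vz = vecs[:, -1]  # principal in-plane axis -> y
    theta = np.arctan2(vz, vy)
    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    out = c @ rot
    if _axis_sign(out[:, 1]) < 0:
        rot = rot @ np.diag([1.0, -1.0, -1.0])  # half-turn about x
        out = c @ rot
    if np.sum(out[left_rows, 0]) < 0:
        rot = rot @ np.diag([-1.0, 1.0, -1.0])  # half-turn about y
    return rot


@dataclass
class ProcrustesResult:
    """Superimposed configurations in the consensus frame."""

    aligned: np.ndarray            # (N, K, 3), unit centroid size
    symmetric: np.ndarray          # (N, K, 3) symmetric components
    centroid_sizes: np.ndarray     # (N,) on the original mm scale
    consensus: np.ndarray          # (K, 3)
    iterations: int
    converged: bool


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized (partial) Procrustes superimposition with object symmetry.

    Parameters
    ----------
    symmetry :
        Bilateral pair/midline structure.  When given, each configuration
        and its reflected, relabelled copy are jointly superimposed and the
        per-specimen symmetric component is exposed; when ``None`` a plain
        GPA is run and the symmetric component equals the aligned shape.
    labels :
        Landmark labels fixing the row order (required with ``symmetry``).
    tol :
        Convergence threshold on the root-mean-square change of the
        consensus between iterations.
    max_iter :
        Iteration cap; exceeding it raises unless ``strict=False``.

    Attributes
    ----------
    consensus_ : (K, 3) mean shape (exactly symmetric when a symmetry map
        is supplied).
    aligned_, symmetric_ : (N, K, 3) training configurations in the
        consensus frame.
    centroid_sizes_ : (N,) original centroid sizes in mm.
    n_iter_, converged_ : convergence metadata.
    """

    def __init__(
        self,
        symmetry: SymmetryMap | None = None,
        labels: list[str] | None = None,
        tol: float = 1e-10,
        max_iter: int = 100,
        strict: bool = True,
    ):
        self.symmetry = symmetry
        self.labels = labels
        self.tol = tol
        self.max_iter = max_iter
        self.strict = strict

    # -- helpers ----------------------------------------------------------
    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], LandmarkConfiguration):
            if self.labels is not None:
                X = [c.reordered(self.labels).coords for c in X]
            else:
                X = [c.coords for c in X]
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ValueError("expected configurations of shape (N, K, 3)")
        return arr

    def _perm(self, k: int) -> np.ndarray | None:
        if self.symmetry is None:
            return None
        if self.labels is None:
            raise ValueError("labels are required when a symmetry map is given")
        if len(self.labels) != k:
            raise ValueError("labels length does not match configurations")
        return self.symmetry.swap_permutation(self.labels)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y=None) -> "GeneralizedProcrustes":
        arr = self._as_array(X)
        n, k, _ = arr.shape
        if n < 2:
            raise ValueError("GPA needs at least two configurations")
        perm = self._perm(k)

        self.centroid_sizes_ = np.array([centroid_size(c) for c in arr])
        scaled = np.stack([_center_unit(c) for c in arr])
        pool = scaled
        if perm is not None:
            mirrored = np.stack([_reflect_relabel(c, perm) for c in scaled])
            pool = np.concatenate([scaled, mirrored])

        consensus = pool[0].copy()
        if perm is not None:
            consensus = 0.5 * (consensus + _reflect_relabel(consensus, perm))
        converged = False
        it = 0
        aligned = pool
        objective: list[float] = []
        for it in range(1, self.max_iter + 1):
            aligned = np.stack([c @ rigid_fit(c, consensus)[0] for c in pool])
            new_consensus = aligned.mean(axis=0)
            if perm is not None:
                new_consensus = 0.5 * (
                    new_consensus + _reflect_relabel(new_consensus, perm)
                )
            objective.append(float(np.sum((aligned - new_consensus) ** 2)))
            change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
            consensus = new_consensus
            if change < self.tol:
                converged = True
                break
        if not converged and self.strict:
            raise RuntimeError(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last consensus change {change:.3e})"
            )
        # gauge fixing: put the consensus in canonical orientation
        if perm is not None:
            left = [l for l, _ in self.symmetry.pairs]
            left_rows = np.array([i for i, lab in enumerate(self.labels) if lab in left])
        else:
            left_rows = None
        canon = _canonical_rotation(consensus, left_rows)
        consensus = (consensus - consensus.mean(axis=0)) @ canon

        # final pass against the converged consensus
        aligned = np.stack([c @ rigid_fit(c, consensus)[0] for c in pool])

        self.consensus_ = consensus
        self.aligned_ = aligned[:n]
        if perm is not None:
            sym = 0.5 * (aligned[:n] + aligned[n:])
            # enforce exact reflect-and-relabel invariance
            self.symmetric_ = 0.5 * (
                sym + np.stack([_reflect_relabel(s, perm) for s in sym])
            )
        else:
            self.symmetric_ = self.aligned_.copy()
        self.n_iter_ = it
        self.converged_ = converged
        self.objective_trace_ = np.array(objective)
        self._perm_ = perm
        return self

    def transform(self, X) -> np.ndarray:
        """Fit new configurations into the frozen consensus frame.

        Each configuration is centred, rescaled to unit centroid size and
        rotated onto the training consensus by a single ordinary Procrustes
        step; the symmetric component is returned.
        """
        if not hasattr(self, "consensus_"):
            raise RuntimeError("GeneralizedProcrustes is not fitted")
        arr = self._as_array(X)
        out = []
        for c in arr:
            u = _center_unit(c)
            a = u @ rigid_fit(u, self.consensus_)[0]
            if self._perm_ is not None:
                m = _reflect_relabel(u, self._perm_)
                am = m @ rigid_fit(m, self.consensus_)[0]
                s = 0.5 * (a + am)
                s = 0.5 * (s + _reflect_relabel(s, self._perm_))
                out.append(s)
            else:
                out.append(a)
        return np.stack(out)

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.symmetric_

    def result(self) -> ProcrustesResult:
        return ProcrustesResult(
            aligned=self.aligned_,
            symmetric=self.symmetric_,
            centroid_sizes=self.centroid_sizes_,
            consensus=self.consensus_,
            iterations=self.n_iter_,
            converged=self.converged_,
        )


def gpa_object_symmetry(
    configs, sym: SymmetryMap, labels: list[str] | None = None, **kw
) -> ProcrustesResult:
    """Functional wrapper around :class:`GeneralizedProcrustes`."""
    if labels is None and configs and isinstance(configs[0], LandmarkConfiguration):
        labels = configs[0].labels
    gpa = GeneralizedProcrustes(symmetry=sym, labels=labels, **kw)
    gpa.fit(configs)
    return gpa.result()


# ---------------------------------------------------------------------------
# Measurement-error Procrustes ANOVA

@dataclass
class AnovaTable:
    """Two-effect decomposition of Procrustes variation (individual, error)."""

    effects: list[tuple[str, float, int, float]]  # (name, SS, df, MS)
    goodall_f: float
    p: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"{'effect':<12}{'SS':>14}{'df':>8}{'MS':>14}"]
        for name, ss, df, ms in self.effects:
            lines.append(f"{name:<12}{ss:>14.6g}{df:>8}{ms:>14.6g}")
        lines.append(f"Goodall F = {self.goodall_f:.4g}, p = {self.p:.4g}")
        return "\n".join(lines)


def procrustes_anova(
    aligned: np.ndarray, specimen_ids: list[str]
) -> AnovaTable:
    """Procrustes ANOVA of digitization error.

    ``aligned`` holds superimposed replicate configurations (N, K, 3);
    ``specimen_ids`` assigns each row to its specimen.  The summed squared
    Procrustes deviations are split into among-individual and
    within-individual (replicate error) effects; degrees of freedom scale
    with the shape-space dimension 3K - 7 (translation, rotation and the
    one-off scaling removed).  Goodall's F refers MS ratios to an F
    distribution.
    """
    arr = np.asarray(aligned, dtype=float)
    n, k, _ = arr.shape
    ids = list(specimen_ids)
    if len(ids) != n:
        raise ValueError("specimen_ids must match the number of configurations")
    uniq = sorted(set(ids), key=ids.index)
    groups = {u: [i for i, s in enumerate(ids) if s == u] for u in uniq}
    n_rep = {u: len(ix) for u, ix in groups.items()}
    if sum(1 for u in uniq if n_rep[u] >= 2) < 2:
        raise ValueError(
            "measurement error is inestimable: need >= 2 replicates "
            "for >= 2 specimens"
        )
    d = 3 * k - 7
    grand = arr.mean(axis=0)
    ss_ind = 0.0
    ss_err = 0.0
    for u, ix in groups.items():
        m = arr[ix].mean(axis=0)
        ss_ind += n_rep[u] * float(np.sum((m - grand) ** 2))
        ss_err += float(np.sum((arr[ix] - m) ** 2))
    df_ind = (len(uniq) - 1) * d
    df_err = sum(r - 1 for r in n_rep.values()) * d
    ms_ind = ss_ind / df_ind
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if ss_err == 0.0:
        f, p = np.inf, 0.0
    else:
        f = ms_ind / ms_err
        p = float(stats.f.sf(f, df_ind, df_err))
    return AnovaTable(
        effects=[
            ("individual", ss_ind, df_ind, ms_ind),
            ("error", ss_err, df_err, ms_err),
        ],
        goodall_f=float(f),
        p=p,
    )


def error_variance_component(table: AnovaTable) -> float:
    """Per-coordinate replicate-error variance estimate (MS of the error effect)."""
    for name, _, _, ms in table.effects:
        if name == "error":
            return float(ms)
    raise ValueError("no error effect in table")


def average_replicates(
    aligned: np.ndarray,
    centroid_sizes: np.ndarray,
    specimen_ids: list[str],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Average aligned replicates into one configuration + one CS per specimen.

    Coordinates are averaged in the common superimposition frame; centroid
    size is averaged on the original millimetre scale.
    """
    arr = np.asarray(aligned, dtype=float)
    cs = np.asarray(centroid_sizes, dtype=float)
    ids = list(specimen_ids)
    uniq = sorted(set(ids), key=ids.index)
    shapes = []
    sizes = []
    for u in uniq:
        ix = [i for i, s in enumerate(ids) if s == u]
        shapes.append(arr[ix].mean(axis=0))
        sizes.append(cs[ix].mean())
    return uniq, np.stack(shapes), np.array(sizes)
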
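"""Fluorophore separation by non-negative matrix factorization.

The 3-excitation x 3-emission reference stack is flattened to a 9 x pixels
matrix V and factorized as V ~ W H with W (9 x k) the per-fluorophore
spectral signatures and H (k x pixels) the abundance maps, both
non-negative. Multiplicative updates minimize the squared Frobenius
residual; the objective is guaranteed non-increasing per iteration, which
tests assert directly. Because NMF is permutation- and scale-ambiguous,
columns of W are rescaled to unit sum (with the inverse scale absorbed
into H) and components are matched to expected fluorophore signatures by
cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SpectralStack
from .synthetic_data import default_mixing_matrix

__all__ = ["UnmixResult", "nmf_multiplicative", "unmix", "fluorophore_flags"]

FLUOROPHORES = ("OGB-1", "EGFP", "tdTomato")


@dataclass
class UnmixResult:
    """Outcome of spectral unmixing.

    ``abundance_maps`` has shape (n_components, height, width) ordered to
    match ``component_names``; ``spectra`` is channels x components with
    unit-sum columns; ``reconstruction_error`` is the relative Frobenius
    residual ||V - WH|| / ||V||.
    """

    abundance_maps: np.ndarray
    spectra: np.ndarray
    reconstruction_error: float
    component_names: tuple[str, ...]
    objective_history: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.abundance_maps < 0) or np.any(self.spectra < 0):
            raise ValueError("abundances and spectra must be non-negative")
        if self.reconstruction_error < 0:
            raise ValueError("reconstruction_error must be >= 0")

    def map_for(self, name: str) -> np.ndarray:
        return self.abundance_maps[self.component_names.index(name)]


def nmf_multiplicative(
    v: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 2000,
    tol: float = 1e-9,
    w_init: np.ndarray | None = None,
    h_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF of ``v`` (m x n) into W (m x k), H (k x n).

    Returns (W, H, objective_history) where the history holds the squared
    Frobenius error after every update sweep. Iteration stops when the
    relative change of the error drops below ``tol``. ``w_init``/``h_init``
    warm-start the factors (e.g. from known fluorophore signatures plus
    their non-negative least-squares abundances); an exact factorization
    is a fixed point of the updates, so a correct warm start is preserved.
    """
    m, n = v.shape
    eps = 1e-12
    scale = np.sqrt(v.mean() / k) if v.mean() > 0 else 1.0
    if w_init is not None:
        w = np.asarray(w_init, dtype=float).copy()
        w[w <= 0] = eps
    else:
        w = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    if h_init is not None:
        h = np.asarray(h_init, dtype=float).copy()
        h[h <= 0] = eps
    else:
        h = rng.uniform(0.1, 1.0, size=(k, n)) * scale
    history = []
    prev = np.inf
    v_norm2 = float(np.linalg.norm(v) ** 2)
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + eps)
        w *= (v @ h.T) / (w @ (h @ h.T) + eps)
        err = float(np.linalg.norm(v - w @ h) ** 2)
        history.append(err)
        if err < 1e-24 * v_norm2:
            break
        if prev < np.inf and prev > 0 and (prev - err) / prev < tol:
            break
        prev = err
    return w, h, np.asarray(history)


def _nnls_abundances(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-pixel non-negative least squares V ~ W H for fixed spectra W."""
    from scipy.optimize import nnls

    h = np.empty((w.shape[1], v.shape[1]))
    for j in range(v.shape[1]):
        h[:, j], _ = nnls(w, v[:, j])
    return h


def _match_components(
    w: np.ndarray, expected: np.ndarray, names: tuple[str, ...]
) -> list[int]:
    """Greedy cosine-similarity assignment of NMF columns to signatures.

    Returns ``perm`` such that column ``perm[j]`` of W corresponds to
    ``names[j]``.
    """
    k = w.shape[1]
    sim = np.zeros((expected.shape[1], k))
    for i in range(expected.shape[1]):
        for j in range(k):
            a, b = expected[:, i], w[:, j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            sim[i, j] = a @ b / (na * nb) if na > 0 and nb > 0 else 0.0
    work = sim.copy()
    perm = [-1] * expected.shape[1]
    for _ in range(min(expected.shape[1], k)):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[int(i)] = int(j)
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return perm


def unmix(
    stack: SpectralStack,
    n_components: int = 3,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-9,
    n_restarts: int = 5,
    expected_spectra: np.ndarray | None = None,
) -> UnmixResult:
    """Separate fluorophore abundance maps from a multispectral stack.

    NMF is non-convex and, with strictly positive spectra, not unique even
    at zero residual (one signature can absorb a scaled copy of another
    with the abundances compensating). Both are handled as guided
    unmixing: one restart is warm-started from the expected fluorophore
    signatures, the remaining ``n_restarts - 1`` from seeded random
    initializations, and among restarts of (near-)equal residual the one
    whose spectra best match the expected signatures wins. When
    ``expected_spectra`` is None the default signature table is used (its
    first ``n_components`` columns).
    """
    v = stack.as_channel_matrix().astype(float)
    if not np.any(v > 0):
        raise ValueError("all-zero stack cannot be unmixed")
    if n_components > v.shape[0]:
        raise ValueError("n_components exceeds the number of channels")
    if expected_spectra is None:
        expected_spectra = default_mixing_matrix()[:, :n_components]

    def _mean_matched_similarity(w: np.ndarray) -> float:
        perm = _match_components(w, expected_spectra,
                                 FLUOROPHORES[:n_components])
        sims = []
        for i, j in enumerate(perm):
            a, b = expected_spectra[:, i], w[:, j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            sims.append(a @ b / (na * nb) if na > 0 and nb > 0 else 0.0)
        return float(np.mean(sims))

    ss = np.random.SeedSequence(seed)
    runs = []
    children = ss.spawn(max(n_restarts, 1))
    for idx, child in enumerate(children):
        if idx == 0:
            w0 = expected_spectra.astype(float)
            h0 = _nnls_abundances(v, w0)
        else:
            w0 = h0 = None
        w, h, hist = nmf_multiplicative(
            v, n_components, np.random.default_rng(child), max_iter, tol,
            w_init=w0, h_init=h0,
        )
        runs.append((float(hist[-1]), _mean_matched_similarity(w), w, h, hist))
    min_err = min(r[0] for r in runs)
    # ties in residual (within 0.1% relative) break toward expected spectra
    slack = 1e-3 * max(min_err, 1e-12 * float(np.linalg.norm(v) ** 2))
    candidates = [r for r in runs if r[0] <= min_err + slack]
    _, _, w, h, hist = max(candidates, key=lambda r: r[1])

    col_sums = w.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    w = w / col_sums
    h = h * col_sums[:, None]

    perm = _match_components(w, expected_spectra, FLUOROPHORES[:n_components])
    w = w[:, perm]
    h = h[perm]

    _, _, hh, ww = stack.data.shape
    err = float(np.linalg.norm(v - w @ h) / np.linalg.norm(v))
    return UnmixResult(
        abundance_maps=h.reshape(n_components, hh, ww),
        spectra=w,
        reconstruction_error=err,
        component_names=FLUOROPHORES[:n_components],
        objective_history=hist,
    )


def fluorophore_flags(
    result: UnmixResult,
    roi_center: tuple[int, int],
    roi_half: int = 3,
    all_centers: np.ndarray | None = None,
    ratio_threshold: float = 0.75,
) -> tuple[bool, bool]:
    """Decide reporter expression (EGFP, tdTomato) for one cell ROI.

    A flag is positive when the mean abundance of that fluorophore inside
    the (2*roi_half+1)^2 window (i) exceeds the background mean + 2
    background SD and (ii) reaches ``ratio_threshold`` times the cell's
    calcium-dye abundance in the same window. Background pixels are those
    outside every ROI in ``all_centers`` (default: outside this ROI only).
    The relative criterion mirrors visual classification — a reporter is
    judged against the cell's overall brightness — and guards against
    spectral bleed-through, which scales with brightness and can clear a
    purely background-based threshold on bright cells.
    """
    maps = {n: result.map_for(n) for n in ("EGFP", "tdTomato")}
    h, w = next(iter(maps.values())).shape
    r0, c0 = roi_center
    if r0 - roi_half < 0 or c0 - roi_half < 0 or r0 + roi_half >= h or c0 + roi_half >= w:
        raise ValueError("ROI window extends beyond the image border")
    if all_centers is None:
        all_centers = np.array([roi_center])
    bg_mask = np.ones((h, w), dtype=bool)
    for r, c in np.atleast_2d(all_centers):
        bg_mask[
            max(0, r - roi_half) : r + roi_half + 1,
            max(0, c - roi_half) : c + roi_half + 1,
        ] = False

    window = np.s_[r0 - roi_half : r0 + roi_half + 1,
                   c0 - roi_half : c0 + roi_half + 1]
    try:
        dye_mean = result.map_for("OGB-1")[window].mean()
    except ValueError:  # no dye component fitted; relative criterion off
        dye_mean = 0.0
    flags = []
    for name in ("EGFP", "tdTomato"):
        m = maps[name]
        roi_mean = m[window].mean()
        bg = m[bg_mask]
        above_bg = roi_mean > bg.mean() + 2.0 * bg.std()
        above_ratio = roi_mean >= ratio_threshold * dye_mean
        flags.append(bool(above_bg and above_ratio))
    return flags[0], flags[1]
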
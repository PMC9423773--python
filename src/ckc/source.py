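"""Minimal DICS beamformer: source-space coherence with a kinematic reference.

At the stimulation frequency, the sensor cross-spectral density (CSD)
C = (1/K) sum_k X_k X_k^H, the sensor-reference cross-spectral vector
c = (1/K) sum_k X_k Y_k*, and the reference power p = (1/K) sum_k |Y_k|^2
are estimated from the same epochs.  For each grid node with (rank-reduced)
lead field L (channels x 2), the unit-gain minimum-variance spatial filter

    W = (L^H C_r^-1 L)^-1 L^H C_r^-1,     C_r = C + reg * mean(diag C) * I

yields a 2-component source estimate; it is scalarized along the dominant
orientation u (leading eigenvector of the source CSD W C W^H), giving node
coherence

    coh = |u^H W c|^2 / ((u^H W C W^H u) * p)

which is the ordinary magnitude-squared coherence of the beamformed source
time course with the reference, hence bounded by [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .epoching import EpochSet
from .forward import LeadField, SourceGrid
from .spectral import SpectralError, _bin_index

logger = logging.getLogger(__name__)


class SourceError(ValueError):
    pass


@dataclass(frozen=True)
class SourceCoherenceMap:
    """Coherence per grid node at the stimulation frequency."""

    values: np.ndarray          # (N,) in [0, 1]
    grid: SourceGrid
    stim_freq: float
    regularization: float
    peak_node: int
    peak_value: float


def csd_at_frequency(epochs: EpochSet, stim_freq: float, snap: bool = False):
    """Sensor CSD matrix, sensor-reference cross vector and reference power.

    All three are averaged over the same epochs at the requested bin.
    Returns ``(csd, cross, ref_power)``.
    """
    if epochs.k < 2:
        raise SourceError("CSD requires at least 2 epochs")
    freqs = np.fft.rfftfreq(epochs.n_samples, 1.0 / epochs.sample_rate)
    bi = _bin_index(freqs, stim_freq, snap)
    x = np.fft.rfft(epochs.meg, axis=-1)[:, :, bi]   # (K, C)
    y = np.fft.rfft(epochs.ref, axis=-1)[:, bi]      # (K,)
    k = epochs.k
    csd = x.T @ x.conj() / k                          # C_ij = E[X_i X_j*], Hermitian PSD
    herm_err = np.max(np.abs(csd - csd.conj().T))
    if herm_err > 1e-8 * max(np.max(np.abs(csd)), 1e-300):
        logger.warning("CSD non-Hermitian (max asymmetry %.3g); symmetrizing",
                       herm_err)
    csd = 0.5 * (csd + csd.conj().T)
    cross = x.T @ y.conj() / k                        # E[X_i Y*] per channel
    ref_power = float(np.mean(np.abs(y) ** 2))
    return csd, cross, ref_power


def reduce_leadfield_rank(block: np.ndarray) -> tuple:
    """Reduce a channels x 3 gain block to its two strongest components.

    SVD of the block; the kept columns are ``U[:, :2] * s[:2]`` (the span of
    the top-2 right-singular orientation directions), with a deterministic
    sign convention: the largest-magnitude element of each kept column is
    positive.  Returns ``(reduced, singular_values)``.
    """
    block = np.asarray(block, dtype=float)
    if not np.all(np.isfinite(block)):
        raise SourceError("non-finite lead-field block")
    if not np.any(block):
        raise SourceError("all-zero lead-field block (silent source)")
    u, s, _ = np.linalg.svd(block, full_matrices=False)
    reduced = u[:, :2] * s[:2]
    for j in range(reduced.shape[1]):
        i = np.argmax(np.abs(reduced[:, j]))
        if reduced[i, j] < 0:
            reduced[:, j] = -reduced[:, j]
    return reduced, s


def reduce_leadfield(lf: LeadField) -> LeadField:
    """Rank-reduce every node of a lead field (skipping silent nodes is an error)."""
    n, c, _ = lf.full.shape
    reduced = np.empty((n, c, 2))
    svals = np.empty((n, 3))
    for i in range(n):
        reduced[i], svals[i] = reduce_leadfield_rank(lf.full[i])
    return replace(lf, reduced=reduced, singular_values=svals)


def dics_coherence_map(csd: np.ndarray, cross: np.ndarray, ref_power: float,
                       leadfield: LeadField,
                       regularization: float = 0.05) -> SourceCoherenceMap:
    """Scan the grid with the DICS spatial filter; coherence per node.

    ``regularization`` is the diagonal-loading fraction of the mean CSD
    diagonal.  Ties at the peak break to the lowest node index.
    """
    if leadfield.reduced is None:
        leadfield = reduce_leadfield(leadfield)
    c = csd.shape[0]
    load = regularization * float(np.mean(np.real(np.diag(csd))))
    cr = csd + load * np.eye(c)
    try:
        ci = linalg.inv(cr)
    except linalg.LinAlgError as err:
        raise SourceError(
            "CSD is singular; increase the diagonal-loading regularization"
        ) from err
    cond = np.linalg.cond(cr)
    if cond > 1e12:
        raise SourceError(
            f"regularized CSD still ill-conditioned (cond={cond:.2g}); "
            "increase the diagonal loading")

    values = np.empty(leadfield.grid.n_nodes)
    if ref_power <= 0:
        values[:] = np.nan
    for i in range(leadfield.grid.n_nodes):
        lf = leadfield.reduced[i]                    # (C, 2)
        lhci = lf.T @ ci                              # (2, C)
        a = lhci @ lf                                 # (2, 2)
        w = np.linalg.solve(a, lhci)                  # (2, C) unit-gain filter
        s2 = w @ csd @ w.conj().T                     # source CSD (2, 2)
        c2 = w @ cross                                # (2,)
        s2 = 0.5 * (s2 + s2.conj().T)
        evals, evecs = np.linalg.eigh(s2)
        u = evecs[:, -1]
        if np.real(u[np.argmax(np.abs(u))]) < 0:
            u = -u
        num = np.abs(np.vdot(u, c2)) ** 2
        den = float(np.real(u.conj() @ s2 @ u)) * ref_power
        values[i] = num / den if den > 0 else 0.0
    values = np.clip(values, 0.0, 1.0, out=values)
    peak = int(np.argmax(values))
    return SourceCoherenceMap(values=values, grid=leadfield.grid,
                              stim_freq=np.nan, regularization=regularization,
                              peak_node=peak, peak_value=float(values[peak]))


def peak_source_location(cmap: SourceCoherenceMap) -> tuple:
    """Coordinates (mm) and value of the map maximum (ties: lowest node index)."""
    if cmap.values.size == 0:
        raise SourceError("empty source map")
    i = int(np.argmax(cmap.values))
    return cmap.grid.nodes[i].copy(), float(cmap.values[i])


def source_ckc(epochs: EpochSet, stim_freq: float, leadfield: LeadField,
               regularization: float = 0.05) -> SourceCoherenceMap:
    """CSD estimation + DICS scan at the stimulation frequency, in one call."""
    csd, cross, ref_power = csd_at_frequency(epochs, stim_freq)
    cmap = dics_coherence_map(csd, cross, ref_power, leadfield, regularization)
    return replace(cmap, stim_freq=stim_freq)
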
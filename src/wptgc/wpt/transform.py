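"""Wavelet packet decomposition with periodized boundaries.

A full binary filter-bank tree built from orthonormal Coiflet filters.
Circular (periodized) convolution keeps the transform exactly orthogonal
for any even signal length, so the sum of all terminal-band
reconstructions matches the input at machine precision.  Terminal nodes
are kept in natural (filter-tree) order; the Gray-code sequency
permutation maps them to ascending frequency position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._coiflets import COIFLET_DEC_LO

__all__ = [
    "WPTDecomposition",
    "BandSignal",
    "wpt_decompose",
    "node_frequency_band",
    "natural_to_frequency_order",
    "extract_band",
    "reconstruct_node",
    "reconstruct_sum",
    "reconstruction_mse",
]


def _filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (lowpass, highpass) analysis filters for a Coiflet."""
    try:
        lo = np.asarray(COIFLET_DEC_LO[wavelet_name], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown wavelet {wavelet_name!r}; available: "
            f"{sorted(COIFLET_DEC_LO)}"
        ) from None
    # quadrature mirror: g[n] = (-1)^n h[L-1-n]
    hi = lo[::-1].copy()
    hi[1::2] *= -1.0
    return lo, hi


def _analysis_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """One periodized analysis step: x (even length N) -> (a, d) of N/2."""
    n = x.size
    if n % 2:
        raise ValueError(f"periodized analysis needs even length, got {n}")
    L = lo.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :]) % n
    xs = x[idx]
    return xs @ lo, xs @ hi


def _synthesis_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Adjoint of `_analysis_step` (exact inverse for orthonormal filters)."""
    n = 2 * a.size
    L = lo.size
    idx = (2 * np.arange(a.size)[:, None] + np.arange(L)[None, :]) % n
    out = np.zeros(n)
    np.add.at(out, idx.ravel(), (a[:, None] * lo[None, :]).ravel())
    np.add.at(out, idx.ravel(), (d[:, None] * hi[None, :]).ravel())
    return out


def natural_to_frequency_order(j: int, i_natural: int) -> int:
    """Map a natural (filter-tree) node index to its frequency position.

    Descending the tree, the spectrum of a highpass branch is mirrored by
    the decimation, so children of every odd-positioned band swap roles.
    The resulting permutation is the inverse binary-reflected Gray code.
    """
    if not 0 <= i_natural < 2 ** j:
        raise ValueError(f"node index {i_natural} out of range for depth {j}")
    k = 0
    for bit_pos in range(j - 1, -1, -1):
        b = (i_natural >> bit_pos) & 1
        k = 2 * k + (b if k % 2 == 0 else 1 - b)
    return k


@dataclass
class WPTDecomposition:
    """Full wavelet packet tree of one signal.

    ``nodes[(j, i)]`` holds the coefficient vector of tree node *i* at
    depth *j* in natural order; depth 0 node is the (padded) signal.
    """

    wavelet_name: str
    levels: int
    nodes: dict[tuple[int, int], np.ndarray]
    fs: float
    original_length: int
    padded_length: int = field(default=0)

    @property
    def band_width(self) -> float:
        """Terminal band width fs / 2**(levels+1) in Hz."""
        return self.fs / 2 ** (self.levels + 1)

    def terminal_nodes(self) -> list[tuple[int, int]]:
        return [(self.levels, i) for i in range(2 ** self.levels)]


def wpt_decompose(signal, wavelet_name: str = "coif5", levels: int = 7,
                  fs: float = 250.0) -> WPTDecomposition:
    """Decompose ``signal`` into a full binary tree of depth ``levels``.

    The signal is zero-padded to the next multiple of ``2**levels`` so
    every analysis step sees an even length; reconstructions are
    truncated back to the original support.
    """
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    min_len = 2 ** levels
    if n < min_len:
        raise ValueError(
            f"signal of length {n} too short for {levels} levels; "
            f"minimum length is {min_len}"
        )
    if levels < 1:
        raise ValueError("levels must be >= 1")
    block = 2 ** levels
    padded = int(np.ceil(n / block)) * block
    if padded != n:
        x = np.concatenate([x, np.zeros(padded - n)])
    lo, hi = _filters(wavelet_name)
    nodes: dict[tuple[int, int], np.ndarray] = {(0, 0): x}
    for j in range(levels):
        for i in range(2 ** j):
            a, d = _analysis_step(nodes[(j, i)], lo, hi)
            nodes[(j + 1, 2 * i)] = a
            nodes[(j + 1, 2 * i + 1)] = d
    return WPTDecomposition(
        wavelet_name=wavelet_name, levels=levels, nodes=nodes, fs=fs,
        original_length=n, padded_length=padded,
    )


def node_frequency_band(j: int, i_natural: int, fs: float) -> tuple[float, float]:
    """Half-open frequency interval [f_lo, f_hi) covered by node (j, i).

    The 2**j intervals of one depth tile [0, fs/2) disjointly once the
    natural order is permuted to frequency (sequency) order.
    """
    k = natural_to_frequency_order(j, i_natural)
    width = fs / 2 ** (j + 1)
    return k * width, (k + 1) * width


@dataclass
class BandSignal:
    """A single narrowband reconstruction w(f, t)."""

    w: np.ndarray
    f_center: float
    band: tuple[float, float]
    node: tuple[int, int, int]  # (depth, i_natural, i_frequency)
    fs: float

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (f_lo <= self.f_center < f_hi):
            raise ValueError(
                f"f_center {self.f_center} outside band [{f_lo}, {f_hi})"
            )


def reconstruct_node(decomp: WPTDecomposition, j: int, i: int) -> np.ndarray:
    """Reconstruct one node to full original length, all siblings zeroed."""
    key = (j, i)
    if key not in decomp.nodes:
        raise KeyError(f"node {key} missing from decomposition")
    lo, hi = _filters(decomp.wavelet_name)
    rec = decomp.nodes[key]
    for _ in range(j):
        zeros = np.zeros_like(rec)
        if i % 2:
            rec = _synthesis_step(zeros, rec, lo, hi)
        else:
            rec = _synthesis_step(rec, zeros, lo, hi)
        i //= 2
    return rec[: decomp.original_length]


def extract_band(decomp: WPTDecomposition, f_center: float) -> BandSignal:
    """Reconstruct the terminal band whose frequency interval holds f_center."""
    nyq = decomp.fs / 2.0
    if not 0 < f_center < nyq:
        raise ValueError(f"f_center must lie in (0, {nyq}), got {f_center}")
    j = decomp.levels
    width = decomp.band_width
    k = int(f_center // width)  # frequency position
    # invert the sequency permutation
    i_natural = next(
        i for i in range(2 ** j) if natural_to_frequency_order(j, i) == k
    )
    w = reconstruct_node(decomp, j, i_natural)
    return BandSignal(
        w=w, f_center=f_center, band=(k * width, (k + 1) * width),
        node=(j, i_natural, k), fs=decomp.fs,
    )


def reconstruct_sum(decomp: WPTDecomposition) -> np.ndarray:
    """Sum of every terminal-node reconstruction (the full inverse)."""
    for key in decomp.terminal_nodes():
        if key not in decomp.nodes:
            raise KeyError(f"terminal node {key} missing")
    lo, hi = _filters(decomp.wavelet_name)
    # invert level by level rather than per-node: identical by linearity,
    # O(levels * N) instead of O(2^levels * N)
    level = [decomp.nodes[(decomp.levels, i)] for i in range(2 ** decomp.levels)]
    for _ in range(decomp.levels):
        level = [
            _synthesis_step(level[2 * i], level[2 * i + 1], lo, hi)
            for i in range(len(level) // 2)
        ]
    return level[0][: decomp.original_length]


def reconstruction_mse(signal, decomp: WPTDecomposition) -> float:
    """Mean squared pointwise error between ``signal`` and the summed bands."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size != decomp.original_length:
        raise ValueError(
            f"length mismatch: signal {x.size} vs decomposition "
            f"{decomp.original_length}"
        )
    rec = reconstruct_sum(decomp)
    return float(np.mean((x - rec) ** 2))
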
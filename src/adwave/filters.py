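"""Filter banks for the dual-tree complex wavelet transform.

A two-channel filter bank is represented as four :class:`FilterPair` objects
(analysis low/high, synthesis low/high).  Taps are stored together with an
integer ``origin`` so a pair ``(taps, origin)`` denotes the filter
``f[n] = taps[n + origin]`` — i.e. tap index ``i`` sits at time ``n = i - origin``.
This makes fractional-delay bookkeeping between the two trees explicit.

The dual tree uses

* level 1: the LeGall/CDF 5/3 biorthogonal pair (exact dyadic-rational taps,
  hence perfect reconstruction to machine precision); tree *b* is tree *a*
  delayed by one input sample, giving the required half-sample offset after
  decimation.
* levels >= 2: Kingsbury's 10-tap Q-shift orthonormal filter for tree *a*
  and its time reverse for tree *b* (quarter- vs three-quarter-sample group
  delay, so the trees stay half a sample apart at every scale).

The published Q-shift taps are given to 8 decimals, which leaves a ~4e-9
orthonormality residual; at import they are Gauss–Newton-projected onto the
paraunitary manifold so that per-tree perfect reconstruction holds to ~1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FilterPair",
    "FilterBank",
    "FilterBankSet",
    "default_filter_bank_set",
    "legall_bank",
    "qshift_bank",
    "paraunitarity_residual",
    "polish_paraunitary",
]


@dataclass(frozen=True, eq=False)
class FilterPair:
    """FIR filter ``f[n] = taps[n + origin]``."""

    taps: np.ndarray
    origin: int

    def delayed(self, d: int = 1) -> "FilterPair":
        """The filter ``z^{-d} F(z)`` (same taps, shifted time origin)."""
        return FilterPair(self.taps, self.origin - d)

    def modulated(self) -> "FilterPair":
        """``F(-z)``: taps multiplied by (-1)^n."""
        signs = np.array([(-1.0) ** (i - self.origin) for i in range(len(self.taps))])
        return FilterPair(self.taps * signs, self.origin)


@dataclass(frozen=True, eq=False)
class FilterBank:
    """One tree's two-channel analysis/synthesis bank."""

    dec_lo: FilterPair
    dec_hi: FilterPair
    rec_lo: FilterPair
    rec_hi: FilterPair

    def delayed(self, d: int = 1) -> "FilterBank":
        # Delaying every analysis filter and advancing every synthesis filter
        # by the same amount preserves perfect reconstruction exactly.
        return FilterBank(
            self.dec_lo.delayed(d),
            self.dec_hi.delayed(d),
            self.rec_lo.delayed(-d),
            self.rec_hi.delayed(-d),
        )


def derive_bank(dec_lo: FilterPair, rec_lo: FilterPair) -> FilterBank:
    """Complete a two-channel bank from its lowpass pair.

    Highpass filters follow the alias-cancelling construction
    ``H1(z) = z^{-1} G0(-z)``, ``G1(z) = z H0(-z)``; perfect reconstruction
    then reduces to the halfband condition ``P(z) + P(-z) = 2`` for
    ``P = G0 H0``, which both shipped lowpass pairs satisfy.
    """
    m_rec = rec_lo.modulated()
    dec_hi = FilterPair(m_rec.taps, m_rec.origin - 1)
    m_dec = dec_lo.modulated()
    rec_hi = FilterPair(m_dec.taps, m_dec.origin + 1)
    return FilterBank(dec_lo, dec_hi, rec_lo, rec_hi)


def legall_bank() -> FilterBank:
    """LeGall/CDF 5/3 biorthogonal bank with exact dyadic taps."""
    dec_lo = FilterPair(np.array([-1.0, 2.0, 6.0, 2.0, -1.0]) / 8.0, 2)
    rec_lo = FilterPair(np.array([1.0, 2.0, 1.0]) / 2.0, 1)
    return derive_bank(dec_lo, rec_lo)


# Kingsbury 10-tap Q-shift lowpass, as published (8 decimal places).
_QSHIFT10_PRINTED = np.array(
    [
        0.03516384,
        0.0,
        -0.08832942,
        0.23389032,
        0.76027237,
        0.58751830,
        0.0,
        -0.11430184,
        0.0,
        0.0,
    ]
)


def paraunitarity_residual(h: np.ndarray) -> float:
    """max_k | sum_n h[n] h[n+2k] - delta_k | — zero for an orthonormal filter."""
    L = len(h)
    return max(
        abs(float(h[: L - 2 * k] @ h[2 * k :]) - (1.0 if k == 0 else 0.0))
        for k in range(L // 2)
    )


def polish_paraunitary(h: np.ndarray, tol: float = 1e-15, max_iter: int = 50) -> np.ndarray:
    """Gauss–Newton projection of ``h`` onto the orthonormal-lowpass manifold.

    Constraints: ``sum_n h[n] h[n+2k] = delta_k`` (paraunitarity) and
    ``sum_n (-1)^n h[n] = 0`` (zero response at Nyquist, so the derived
    highpass annihilates constants exactly).
    """
    h = np.asarray(h, dtype=float).copy()
    L = len(h)
    alt = np.array([(-1.0) ** n for n in range(L)])
    for _ in range(max_iter):
        r = np.array(
            [float(h[: L - 2 * k] @ h[2 * k :]) - (1.0 if k == 0 else 0.0) for k in range(L // 2)]
            + [float(alt @ h)]
        )
        if np.max(np.abs(r)) < tol:
            break
        J = np.zeros((L // 2 + 1, L))
        for k in range(L // 2):
            for n in range(L - 2 * k):
                J[k, n] += h[n + 2 * k]
                J[k, n + 2 * k] += h[n]
        J[L // 2] = alt
        h -= np.linalg.lstsq(J, r, rcond=None)[0]
    return h


_QSHIFT10 = polish_paraunitary(_QSHIFT10_PRINTED)


def qshift_bank(taps: np.ndarray | None = None, origin: int = 5) -> FilterBank:
    """Orthonormal Q-shift bank; synthesis lowpass is the time-reversed analysis."""
    h0 = _QSHIFT10 if taps is None else np.asarray(taps, dtype=float)
    dec_lo = FilterPair(h0, origin)
    rec_lo = FilterPair(h0[::-1].copy(), len(h0) - 1 - origin)
    return derive_bank(dec_lo, rec_lo)


@dataclass(frozen=True, eq=False)
class FilterBankSet:
    """The four banks driving a dual tree: level-1 and Q-shift, trees a/b."""

    level1_a: FilterBank
    level1_b: FilterBank
    qshift_a: FilterBank
    qshift_b: FilterBank

    def bank(self, tree: str, level: int) -> FilterBank:
        if level == 0:
            return self.level1_a if tree == "a" else self.level1_b
        return self.qshift_a if tree == "a" else self.qshift_b


def banks_equivalent(a: FilterBankSet, b: FilterBankSet) -> bool:
    """Structural equality of two bank sets (taps and origins)."""
    if a is b:
        return True
    for name in ("level1_a", "level1_b", "qshift_a", "qshift_b"):
        ba, bb = getattr(a, name), getattr(b, name)
        for ch in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
            fa, fb = getattr(ba, ch), getattr(bb, ch)
            if fa.origin != fb.origin or not np.array_equal(fa.taps, fb.taps):
                return False
    return True


def default_filter_bank_set() -> FilterBankSet:
    lg = legall_bank()
    return FilterBankSet(
        level1_a=lg,
        level1_b=lg.delayed(1),
        qshift_a=qshift_bank(_QSHIFT10),
        qshift_b=qshift_bank(_QSHIFT10[::-1].copy()),
    )
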
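"""Pairwise evolutionary distances under p, K2P, TN93 and GTR corrections.

All four distances share a single counting step (:func:`pair_counts` /
:func:`_count_tensor`) performed under **pairwise deletion**: for each pair of
sequences only the sites where *both* carry a determinate base (A/C/G/T) are
compared; gaps, ``N``/``?`` and IUPAC ambiguity codes contribute nothing.

Saturated pairs (a correction's log/eigenvalue domain violated) and pairs with
no overlapping determinate sites are *flagged undefined* in the resulting
:class:`DistanceMatrix` rather than raising: a single saturated pair must not
abort a 290-sequence analysis.  Downstream gap discovery treats undefined
entries as absent pairs.

Model summary
-------------
p      observed proportion of differing sites.
K2P    Kimura 2-parameter: transitions (P) vs transversions (Q), equal base
       frequencies;  d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].
TN93   Tamura-Nei: separate purine (A<->G, P1) and pyrimidine (C<->T, P2)
       transition classes, unequal base frequencies.
GTR    general time-reversible pairwise estimator
       d = -tr(Pi log(Pi^-1 F)) on the symmetrised divergence matrix F.

K2P and TN93 optionally take a gamma rate-heterogeneity shape ``alpha`` and a
proportion of invariable sites ``p_inv``; both are user-supplied (e.g. from a
prior model-selection run), never estimated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import MISSING_CODE, MultipleAlignment, _ENCODE

__all__ = [
    "PairCounts",
    "DistanceModelSpec",
    "DistanceMatrix",
    "NoOverlapError",
    "MODELS",
    "pair_counts",
    "p_distance",
    "k2p_distance",
    "tn93_distance",
    "gtr_distance",
    "build_distance_matrix",
    "distance_histogram",
]

MODELS = ("p", "k2p", "tn93", "gtr")

_PURINES = (0, 2)  # A, G
_PYRIMIDINES = (1, 3)  # C, T


class NoOverlapError(ValueError):
    """A sequence pair shares no site where both are determinate."""


@dataclass(frozen=True)
class DistanceModelSpec:
    """Which correction to apply and its optional rate-heterogeneity parameters.

    ``alpha`` is the gamma shape (>0); ``p_inv`` the proportion of invariable
    sites (in [0,1)).  ``frequency_mode`` selects whether TN93/GTR base
    frequencies come from each pair's shared sites (``pairwise``, the default,
    consistent with pairwise deletion) or from the whole alignment
    (``global``).
    """

    model: str = "p"
    alpha: float | None = None
    p_inv: float | None = None
    frequency_mode: str = "pairwise"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.p_inv is not None and not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must be in [0, 1)")
        if self.frequency_mode not in ("pairwise", "global"):
            raise ValueError("frequency_mode must be 'pairwise' or 'global'")


@dataclass(frozen=True)
class PairCounts:
    """Site counts for one sequence pair under pairwise deletion.

    ``p1``/``p2`` are the purine- and pyrimidine-transition proportions, ``q``
    the transversion proportion, so ``p1 + p2 + q == n_diff / n_valid``.
    ``fmat[x, y]`` is the fraction of valid sites with state ``x`` in the first
    sequence and ``y`` in the second (states ordered A, C, G, T);
    ``base_freqs`` are the pair's average base frequencies.
    """

    n_valid: int
    n_diff: int
    p1: float
    p2: float
    q: float
    base_freqs: tuple[float, float, float, float]
    fmat: np.ndarray = field(repr=False)

    @property
    def p(self) -> float:
        return self.n_diff / self.n_valid


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with an explicit defined-entry mask.

    ``d[i, j]`` is meaningful only where ``defined[i, j]`` is True; undefined
    entries (no overlap, saturation) hold NaN and are never silently zero.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    defined: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.defined.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if not np.allclose(np.diagonal(self.d), 0):
            raise ValueError("diagonal must be zero")
        dd = np.where(self.defined, self.d, 0.0)
        if not np.allclose(dd, dd.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(dd < 0):
            raise ValueError("defined distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Defined off-diagonal distances, each unordered pair once."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.d[iu]
        return vals[self.defined[iu]]

    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int((~self.defined[iu]).sum())

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        index = {sid: k for k, sid in enumerate(self.ids)}
        sel = np.array([index[i] for i in ids])
        return DistanceMatrix(
            tuple(ids), self.d[np.ix_(sel, sel)], self.defined[np.ix_(sel, sel)], self.model
        )

    # ---- export -----------------------------------------------------------
    def to_phylip(self, dest: Union[str, Path, IO[str]]) -> None:
        """Square PHYLIP matrix; undefined entries written as ``-1.0``."""
        out = np.where(self.defined, self.d, -1.0)
        lines = [f"{self.n}\n"]
        for sid, row in zip(self.ids, out):
            lines.append(sid + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")
        text = "".join(lines)
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered pair (id1, id2, model, distance, defined)."""
        i, j = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "id1": [self.ids[a] for a in i],
                "id2": [self.ids[b] for b in j],
                "model": self.model,
                "distance": self.d[i, j],
                "defined": self.defined[i, j],
            }
        )


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _encode_seq(s: str) -> np.ndarray:
    buf = np.frombuffer(s.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)
    out = _ENCODE[buf]
    if np.any(out == 255):
        bad = s[int(np.argmax(out == 255))]
        raise ValueError(f"illegal character {bad!r} in sequence")
    return out


def _count_tensor(enc: np.ndarray) -> np.ndarray:
    """All-pairs divergence counts: ``F[i, j, x, y]`` = number of sites with
    state x in sequence i and y in sequence j (determinate in both)."""
    n = enc.shape[0]
    ind = [(enc == s).astype(np.float64) for s in range(4)]
    F = np.empty((n, n, 4, 4))
    for x in range(4):
        for y in range(4):
            F[:, :, x, y] = ind[x] @ ind[y].T
    return F


def pair_counts(s1: str, s2: str) -> PairCounts:
    """Count divergence classes for one aligned pair (pairwise deletion).

    Raises :class:`NoOverlapError` when no site is determinate in both.
    """
    a, b = _encode_seq(s1), _encode_seq(s2)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned length")
    valid = (a != MISSING_CODE) & (b != MISSING_CODE)
    nv = int(valid.sum())
    if nv == 0:
        raise NoOverlapError("sequence pair shares no determinate sites")
    av, bv = a[valid], b[valid]
    fcnt = np.zeros((4, 4))
    np.add.at(fcnt, (av, bv), 1)
    return _counts_from_fmat(fcnt)


def _counts_from_fmat(fcnt: np.ndarray) -> PairCounts:
    nv = int(fcnt.sum())
    ndiff = nv - int(np.trace(fcnt))
    p1 = (fcnt[0, 2] + fcnt[2, 0]) / nv
    p2 = (fcnt[1, 3] + fcnt[3, 1]) / nv
    q = sum(fcnt[x, y] + fcnt[y, x] for x in _PURINES for y in _PYRIMIDINES) / nv
    freqs = (fcnt.sum(axis=1) + fcnt.sum(axis=0)) / (2 * nv)
    return PairCounts(
        n_valid=nv,
        n_diff=ndiff,
        p1=float(p1),
        p2=float(p2),
        q=float(q),
        base_freqs=tuple(float(f) for f in freqs),
        fmat=fcnt / nv,
    )


# ---------------------------------------------------------------------------
# corrections (array-safe numeric kernels; NaN marks saturation)
# ---------------------------------------------------------------------------

def _neglog_term(x: np.ndarray, alpha: float | None) -> np.ndarray:
    """-ln(x), or its gamma-rate analogue alpha*(x^(-1/alpha) - 1); NaN where x <= 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(x > 0, -np.log(x) if alpha is None else alpha * (x ** (-1.0 / alpha) - 1.0), np.nan)
    return out


def _k2p_kernel(P, Q, alpha=None, p_inv=None):
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    scale = 1.0
    if p_inv:
        P = P / (1.0 - p_inv)
        Q = Q / (1.0 - p_inv)
        scale = 1.0 - p_inv
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    d = 0.5 * _neglog_term(w1, alpha) + 0.25 * _neglog_term(w2, alpha)
    return scale * d


def _tn93_kernel(p1, p2, q, freqs, alpha=None, p_inv=None):
    """freqs has shape (..., 4) ordered A,C,G,T."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q = np.asarray(q, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    scale = 1.0
    if p_inv:
        p1, p2, q = (v / (1.0 - p_inv) for v in (p1, p2, q))
        scale = 1.0 - p_inv
    pA, pC, pG, pT = (freqs[..., k] for k in range(4))
    pR = pA + pG
    pY = pC + pT
    with np.errstate(invalid="ignore", divide="ignore"):
        k1 = 2.0 * pA * pG / pR
        k2 = 2.0 * pT * pC / pY
        k3 = 2.0 * (pR * pY - pA * pG * pY / pR - pT * pC * pR / pY)
        x1 = 1.0 - p1 / k1 - q / (2.0 * pR)
        x2 = 1.0 - p2 / k2 - q / (2.0 * pY)
        x3 = 1.0 - q / (2.0 * pR * pY)
        # absent substitution classes (k == 0 with matching proportion 0)
        # contribute nothing; k == 0 with nonzero proportion is degenerate.
        t1 = np.where(k1 > 0, k1 * _neglog_term(np.where(k1 > 0, x1, 1.0), alpha), np.where(p1 > 0, np.nan, 0.0))
        t2 = np.where(k2 > 0, k2 * _neglog_term(np.where(k2 > 0, x2, 1.0), alpha), np.where(p2 > 0, np.nan, 0.0))
        t3 = k3 * _neglog_term(x3, alpha)
        d = t1 + t2 + t3
        d = np.where((pR > 0) & (pY > 0), d, np.where(q > 0, np.nan, 0.0))
    return scale * d


def _gtr_kernel(fmat: np.ndarray) -> np.ndarray:
    """Batched GTR pairwise estimator; ``fmat`` has shape (..., 4, 4) of
    divergence proportions.  Returns NaN where the matrix log is undefined."""
    F = 0.5 * (fmat + np.swapaxes(fmat, -1, -2))
    pi = F.sum(axis=-1)  # (..., 4) marginal frequencies
    ok = np.all(pi > 0, axis=-1)
    pi_safe = np.where(pi > 0, pi, 1.0)
    s = 1.0 / np.sqrt(pi_safe)
    # similar symmetric matrix S = Pi^-1/2 F Pi^-1/2
    S = F * s[..., :, None] * s[..., None, :]
    lam, U = np.linalg.eigh(S)
    pos = np.all(lam > 0, axis=-1) & ok
    lam_safe = np.where(lam > 0, lam, 1.0)
    with np.errstate(invalid="ignore"):
        logS_diag = np.einsum("...ik,...k,...ik->...i", U, np.log(lam_safe), U)
        d = -np.einsum("...i,...i->...", pi, logS_diag)
    d = np.where(pos, d, np.nan)
    # numerically tiny negatives at zero divergence
    return np.where(np.isnan(d), np.nan, np.maximum(d, 0.0))


# ---------------------------------------------------------------------------
# public per-pair operations
# ---------------------------------------------------------------------------

def p_distance(c: PairCounts) -> float:
    """Observed proportion of differing sites."""
    return c.n_diff / c.n_valid


def k2p_distance(c: PairCounts, spec: DistanceModelSpec | None = None) -> float:
    """Kimura 2-parameter distance; NaN when the pair is saturated."""
    spec = spec or DistanceModelSpec("k2p")
    return float(_k2p_kernel(c.p1 + c.p2, c.q, spec.alpha, spec.p_inv))


def tn93_distance(c: PairCounts, spec: DistanceModelSpec | None = None) -> float:
    """Tamura-Nei (1993) distance; NaN when saturated.

    Raises ``ValueError`` on degenerate composition (no purines or no
    pyrimidines among the pair's valid sites while transversions are present).
    """
    spec = spec or DistanceModelSpec("tn93")
    pR = c.base_freqs[0] + c.base_freqs[2]
    pY = c.base_freqs[1] + c.base_freqs[3]
    if (pR == 0 or pY == 0) and c.q > 0:
        raise ValueError("degenerate base composition: one purine/pyrimidine class absent")
    return float(_tn93_kernel(c.p1, c.p2, c.q, np.asarray(c.base_freqs), spec.alpha, spec.p_inv))


def gtr_distance(c: PairCounts) -> float:
    """General-time-reversible pairwise distance -tr(Pi log(Pi^-1 F));
    NaN when an eigenvalue of the symmetrised divergence matrix is <= 0 or a
    base is absent from the pair."""
    return float(_gtr_kernel(c.fmat))


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_distance_matrix(
    aln: MultipleAlignment, spec: DistanceModelSpec | str = "p"
) -> DistanceMatrix:
    """All-pairs distance matrix under the selected correction.

    Pairwise deletion throughout; undefined entries (no overlap or saturation)
    are flagged in ``defined`` and hold NaN.  Requires >= 2 sequences.
    """
    if isinstance(spec, str):
        spec = DistanceModelSpec(spec)
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")

    enc = aln.encoded()
    F = _count_tensor(enc)  # (n, n, 4, 4) counts
    nv = F.sum(axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        nv_safe = np.where(nv > 0, nv, 1.0)
        fprop = F / nv_safe[:, :, None, None]
        ndiff = nv - np.trace(F, axis1=2, axis2=3)
        p1 = (F[:, :, 0, 2] + F[:, :, 2, 0]) / nv_safe
        p2 = (F[:, :, 1, 3] + F[:, :, 3, 1]) / nv_safe
        q = sum(F[:, :, x, y] + F[:, :, y, x] for x in _PURINES for y in _PYRIMIDINES) / nv_safe

        if spec.model == "p":
            d = ndiff / nv_safe
        elif spec.model == "k2p":
            d = _k2p_kernel(p1 + p2, q, spec.alpha, spec.p_inv)
        elif spec.model == "tn93":
            freqs = _pair_freqs(F, nv_safe, aln, spec)
            d = _tn93_kernel(p1, p2, q, freqs, spec.alpha, spec.p_inv)
        else:  # gtr
            if spec.frequency_mode == "pairwise":
                d = _gtr_kernel(fprop)
            else:
                d = _gtr_kernel(fprop)  # frequencies are intrinsic to fmat

    defined = (nv > 0) & np.isfinite(d)
    defined &= defined.T
    np.fill_diagonal(defined, True)
    d = np.asarray(d, dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    # exact symmetry despite floating-point evaluation order
    d = np.where(defined, (np.nan_to_num(d) + np.nan_to_num(d).T) / 2.0, np.nan)
    return DistanceMatrix(tuple(aln.ids), d, defined, model=spec.model)


def _pair_freqs(F, nv_safe, aln, spec) -> np.ndarray:
    if spec.frequency_mode == "pairwise":
        return (F.sum(axis=3) + F.sum(axis=2)) / (2.0 * nv_safe[:, :, None])
    enc = aln.encoded()
    counts = np.array([(enc == s).sum() for s in range(4)], dtype=float)
    g = counts / counts.sum()
    n = aln.n_sequences
    return np.broadcast_to(g, (n, n, 4))


def distance_histogram(dm: DistanceMatrix, bin_width: float) -> pd.DataFrame:
    """Frequency table of defined pairwise distances in half-open bins
    ``[k*w, (k+1)*w)`` — the data behind ranked-distance / histogram plots."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = dm.condensed()
    # nudge guards against 0.30/0.1 -> 2.9999... landing in the wrong bin
    idx = np.floor(vals / bin_width + 1e-9).astype(int)
    counts = pd.Series(idx).value_counts().sort_index()
    return pd.DataFrame(
        {
            "bin_left": counts.index * bin_width,
            "bin_right": (counts.index + 1) * bin_width,
            "count": counts.values,
        }
    ).reset_index(drop=True)
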
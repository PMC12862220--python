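"""Chromatin-state segmentation from binned epigenomic tracks.

The model is a K-state hidden Markov model over fixed 200-bp bins whose
emissions are products of independent Bernoulli variables, one per mark
(ATAC, H3K4me3, H3K27ac, H3K27me3).  Tracks are first binarized against a
genome-wide Poisson background, the HMM is trained by Baum–Welch on the
pooled larva + adult sequences (one observation sequence per chromosome per
stage), bins are labelled by posterior (max-marginal) decoding, and states
are collapsed into five regulatory categories plus quiescent:

* ``Pois`` — poised/bivalent: H3K4me3 together with H3K27me3;
* ``Act_promoter`` — open chromatin with H3K27ac and H3K4me3;
* ``Act_enhancer`` — open chromatin with H3K27ac but no H3K4me3;
* ``Rep`` — H3K27me3 without accessibility;
* ``ATAC`` — accessible chromatin with no histone mark;
* ``Qui`` — no signal.

Rules are applied in that precedence order, so a profile satisfying several
definitions gets the first matching category; the rule set is total over all
16 binary mark profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .config import CATEGORIES, MARKS, N_MARKS, child_rng

_EMISSION_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize(
    counts_by_chrom: dict[str, np.ndarray], p_threshold: float = 1e-4
) -> dict[str, np.ndarray]:
    """Binarize binned mark counts against a genome-wide Poisson background.

    A mark is called present in a bin iff the upper-tail probability
    ``P(X >= c)`` under ``Poisson(lambda)`` is below ``p_threshold``, where
    ``lambda`` is that mark's mean count over all bins of the stage.
    """
    stacked = np.concatenate([np.asarray(v) for v in counts_by_chrom.values()], axis=0)
    if np.any(stacked < 0):
        raise ValueError("counts must be non-negative")
    lam = stacked.mean(axis=0)
    for m, l in zip(MARKS, lam):
        if l == 0:
            warnings.warn(f"mark {m} has an all-zero track; binarized as all-absent")
    out: dict[str, np.ndarray] = {}
    for chrom, counts in counts_by_chrom.items():
        counts = np.asarray(counts)
        present = np.zeros(counts.shape, dtype=bool)
        nz = lam > 0
        # P(X >= c) = sf(c - 1)
        present[:, nz] = poisson.sf(counts[:, nz] - 1, lam[nz]) < p_threshold
        out[chrom] = present
    return out


# ---------------------------------------------------------------------------
# the HMM
# ---------------------------------------------------------------------------

@dataclass
class BernoulliHMM:
    """K-state HMM with product-Bernoulli emissions over binary mark vectors.

    Attributes
    ----------
    pi : (K,) initial state distribution
    A : (K, K) transition matrix, rows summing to 1
    E : (K, M) per-state Bernoulli emission probabilities, one per mark
    loglik_history : per-iteration total log-likelihood from the last fit
    """

    n_states: int
    pi: np.ndarray | None = None
    A: np.ndarray | None = None
    E: np.ndarray | None = None
    loglik_history: list = field(default_factory=list)

    # -- likelihood machinery -------------------------------------------------

    def _log_b(self, x: np.ndarray) -> np.ndarray:
        """(T, K) log emission likelihoods for a binary (T, M) sequence."""
        e = np.clip(self.E, _EMISSION_FLOOR, 1 - _EMISSION_FLOOR)
        return x @ np.log(e).T + (1 - x) @ np.log1p(-e).T

    def _forward_backward(self, x: np.ndarray):
        """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
        logb = self._log_b(x)
        b = np.exp(logb - logb.max(axis=1, keepdims=True))
        T, K = b.shape
        alpha = np.empty((T, K))
        c = np.empty(T)
        alpha[0] = self.pi * b[0]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ self.A) * b[t]
            c[t] = alpha[t].sum()
            alpha[t] /= c[t]
        beta = np.empty((T, K))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (self.A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        # summed two-slice marginals, vectorized over t
        xi_sum = self.A * (alpha[:-1].T @ (b[1:] * beta[1:] / c[1:, None]))
        loglik = np.log(c).sum() + logb.max(axis=1).sum()
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite likelihood in forward-backward")
        return gamma, xi_sum, loglik

    # -- training -------------------------------------------------------------

    def fit(
        self,
        sequences: list[np.ndarray],
        seed: int = 0,
        max_iter: int = 200,
        tol: float = 1e-4,
    ) -> "BernoulliHMM":
        """Baum–Welch EM over independent binary observation sequences.

        Initialization: uniform pi, sticky random transitions, emissions
        jittered around the pooled empirical mark frequencies.  Stops when the
        relative log-likelihood change falls below ``tol`` or after
        ``max_iter`` iterations; the log-likelihood is non-decreasing.
        """
        seqs = [np.asarray(s, float) for s in sequences]
        if not seqs:
            raise ValueError("need at least one observation sequence")
        if any(s.ndim != 2 or s.shape[1] != N_MARKS for s in seqs):
            raise ValueError(f"each sequence must be (T, {N_MARKS}) binary")
        K = self.n_states
        rng = child_rng(seed, "hmm-init")
        freq = np.concatenate(seqs).mean(axis=0)
        self.pi = np.full(K, 1.0 / K)
        a = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(a, 0.9)
        self.A = a / a.sum(axis=1, keepdims=True)
        self.E = np.clip(freq + rng.uniform(-0.25, 0.25, size=(K, N_MARKS)), 0.02, 0.98)
        self.loglik_history = []
        prev = -np.inf
        for _ in range(max_iter):
            pi_acc = np.zeros(K)
            xi_acc = np.zeros((K, K))
            e_num = np.zeros((K, N_MARKS))
            e_den = np.zeros(K)
            total_ll = 0.0
            for idx, x in enumerate(seqs):
                try:
                    gamma, xi_sum, ll = self._forward_backward(x)
                except FloatingPointError as err:
                    raise FloatingPointError(
                        f"non-finite likelihood on sequence {idx}"
                    ) from err
                total_ll += ll
                pi_acc += gamma[0]
                xi_acc += xi_sum
                e_num += gamma.T @ x
                e_den += gamma.sum(axis=0)
            self.loglik_history.append(total_ll)
            # M-step
            self.pi = pi_acc / pi_acc.sum()
            self.A = xi_acc / np.maximum(xi_acc.sum(axis=1, keepdims=True), 1e-300)
            self.E = np.clip(e_num / np.maximum(e_den[:, None], 1e-300),
                             _EMISSION_FLOOR, 1 - _EMISSION_FLOOR)
            if np.isfinite(prev) and abs(total_ll - prev) < tol * abs(prev):
                break
            prev = total_ll
        return self

    # -- inference ------------------------------------------------------------

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """(T, K) posterior state probabilities (rows sum to 1)."""
        x = np.asarray(x, float)
        if x.ndim != 2 or x.shape[1] != N_MARKS:
            raise ValueError(f"sequence must be (T, {N_MARKS})")
        gamma, _, _ = self._forward_backward(x)
        return gamma

    def decode(self, x: np.ndarray, method: str = "posterior") -> np.ndarray:
        """Per-bin state labels (0-based) by max-marginal or Viterbi decoding."""
        x = np.asarray(x, float)
        if x.ndim != 2 or x.shape[1] != N_MARKS:
            raise ValueError(f"sequence must be (T, {N_MARKS})")
        if method == "posterior":
            return np.argmax(self.posteriors(x), axis=1)
        if method == "viterbi":
            return self._viterbi(x)
        raise ValueError(f"unknown decoding method {method!r}")

    def _viterbi(self, x: np.ndarray) -> np.ndarray:
        logb = self._log_b(x)
        log_a = np.log(np.maximum(self.A, 1e-300))
        T, K = logb.shape
        delta = np.log(np.maximum(self.pi, 1e-300)) + logb[0]
        psi = np.zeros((T, K), dtype=int)
        for t in range(1, T):
            cand = delta[:, None] + log_a
            psi[t] = np.argmax(cand, axis=0)
            delta = cand[psi[t], np.arange(K)] + logb[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1, path[t + 1]]
        return path

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "E": self.E.tolist(),
            "marks": list(MARKS),
            "category_of_state": collapse_states(self.E),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BernoulliHMM":
        m = cls(n_states=int(d["n_states"]))
        m.pi = np.asarray(d["pi"], float)
        m.A = np.asarray(d["A"], float)
        m.E = np.asarray(d["E"], float)
        return m


def fit_hmm(
    binarized_by_stage: dict[str, dict[str, np.ndarray]],
    k: int = 8,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> BernoulliHMM:
    """Fit one model on sequences pooled over stages (one per chromosome per stage)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = [
        np.asarray(arr, float)
        for stage in sorted(binarized_by_stage)
        for _, arr in sorted(binarized_by_stage[stage].items())
    ]
    return BernoulliHMM(n_states=k).fit(seqs, seed=seed, max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# state collapse and gene-level assignment
# ---------------------------------------------------------------------------

def profile_category(profile) -> str:
    """Map one binary (ATAC, H3K4me3, H3K27ac, H3K27me3) presence profile."""
    a, k4, k27ac, k27me3 = (bool(v) for v in profile)
    if k4 and k27me3:
        return "Pois"
    if a and k27ac and k4:
        return "Act_promoter"
    if a and k27ac and not k4:
        return "Act_enhancer"
    if k27me3 and not a:
        return "Rep"
    if a and not k4 and not k27ac and not k27me3:
        return "ATAC"
    return "Qui"


def collapse_states(emissions: np.ndarray, threshold: float = 0.5) -> list[str]:
    """Category per state: threshold emissions into a presence profile, apply rules."""
    e = np.asarray(emissions, float)
    return [profile_category(row > threshold) for row in e]


def decode_stage(
    model: BernoulliHMM, binarized: dict[str, np.ndarray], method: str = "posterior"
) -> dict[str, np.ndarray]:
    """Per-chromosome 0-based state labels for one stage."""
    return {chrom: model.decode(arr, method=method) for chrom, arr in sorted(binarized.items())}


def categories_per_bin(
    states_by_chrom: dict[str, np.ndarray], category_of_state: list[str]
) -> dict[str, np.ndarray]:
    cat_idx = np.array([CATEGORIES.index(c) for c in category_of_state])
    return {chrom: cat_idx[s] for chrom, s in states_by_chrom.items()}


def assign_gene_category(
    category_idx_by_chrom: dict[str, np.ndarray],
    genes: pd.DataFrame,
    bin_bp: int = 200,
    window_up: int = 5000,
) -> pd.Series:
    """Per-gene category over the transcription-oriented [TSS - 5 kb, TES] window.

    The gene's category is the highest-precedence category among overlapped
    bins (precedence = the CATEGORIES order, Pois first).
    """
    out = {}
    for row in genes.itertuples(index=False):
        if row.chrom not in category_idx_by_chrom:
            raise ValueError(f"gene {row.gene_id} on unknown chromosome {row.chrom}")
        cats = category_idx_by_chrom[row.chrom]
        n_bins = cats.size
        if row.strand == "+":
            lo, hi = row.start - window_up, row.end
        else:
            lo, hi = row.start, row.end + window_up
        b0 = max(lo // bin_bp, 0)
        b1 = min(-(-hi // bin_bp), n_bins)  # ceil division, clipped
        if b1 <= b0:
            raise ValueError(f"gene {row.gene_id} window is empty after clipping")
        out[row.gene_id] = CATEGORIES[int(cats[b0:b1].min())]
    return pd.Series(out, name="category")


# ---------------------------------------------------------------------------
# cross-stage transitions
# ---------------------------------------------------------------------------

def category_transitions(
    labels_from: pd.Series, labels_to: pd.Series, subset=None
) -> dict:
    """Forward/backward category transition tables between two stages.

    ``labels_from``/``labels_to`` map the same units (genes, or bins) to
    categories.  The forward table row ``c`` gives, among units in category
    ``c`` at the first stage, the fraction holding each category at the second
    stage; the ``transitioned`` vector is the off-diagonal row sum.
    """
    if subset is not None:
        subset = list(subset)
        missing = [u for u in subset if u not in labels_from.index or u not in labels_to.index]
        if missing:
            raise ValueError(f"units absent from a segmentation: {missing[:5]}")
        labels_from = labels_from.loc[subset]
        labels_to = labels_to.loc[subset]
    else:
        common = labels_from.index.intersection(labels_to.index)
        labels_from = labels_from.loc[common]
        labels_to = labels_to.loc[common]

    def _table(a: pd.Series, b: pd.Series) -> pd.DataFrame:
        counts = pd.crosstab(a, b).reindex(
            index=list(CATEGORIES), columns=list(CATEGORIES), fill_value=0
        )
        row_sums = counts.sum(axis=1)
        frac = counts.div(row_sums.replace(0, np.nan), axis=0)
        return frac

    forward = _table(labels_from, labels_to)
    backward = _table(labels_to, labels_from)
    transitioned_fwd = 1.0 - pd.Series(np.diag(forward), index=forward.index)
    transitioned_bwd = 1.0 - pd.Series(np.diag(backward), index=backward.index)
    return {
        "forward": forward,
        "backward": backward,
        "transitioned_forward": transitioned_fwd,
        "transitioned_backward": transitioned_bwd,
    }
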
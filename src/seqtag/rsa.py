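"""Representational similarity analysis of token-evoked spatial patterns.

Per-token response patterns (epoch samples x channels, vectorized) are noise
whitened and centered, then compared with a cross-validated correlation
distance: trials are split into stratified folds and the distance between two
tokens is 1 minus the symmetrized correlation between token-mean patterns
estimated on independent train/validation partitions.  The resulting
representational dissimilarity matrix (RDM) is embedded in 2-D by classical
(Torgerson) scaling and compared against binary model RDMs for three coding
schemes: transitional probability (low vs high TP), ordinal position, and
unit identity.

Category structure is quantified by a channel-resampling contrast: channels
are drawn with replacement, token-pair Pearson similarities are Fisher
transformed and averaged over within- and between-category cell sets, and the
resampled averages are compared with a two-sided Wilcoxon rank-sum test; a
Friedman test compares the effect across electrode sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import LedoitWolf
from sklearn.model_selection import StratifiedKFold

from .recording import NeuralRecording
from .streams import TokenStream, UnitInventory

__all__ = [
    "PatternSet",
    "RDM",
    "SchemeModel",
    "ContrastResult",
    "PatternWhitener",
    "CrossValidatedRDM",
    "ClassicalMDS",
    "epoch_patterns",
    "whiten_and_center",
    "crossval_rdm",
    "embed_2d",
    "build_scheme_model",
    "model_rdm_comparison",
    "resampled_contrast",
    "friedman_across_sets",
]

SCHEMES = ("tp", "ordinal", "identity")


@dataclass
class PatternSet:
    """Single-trial spatial patterns: ``X`` is trials x features.

    Features are ordered channel-block by channel-block, each block holding
    ``samples_per_channel`` consecutive samples, so channel resampling can
    operate on blocks.
    """

    X: np.ndarray
    tokens: list[str]
    channel_ids: list[str]
    samples_per_channel: int
    electrode_set: str = ""
    window_s: tuple[float, float] = (0.0, 0.25)
    condition: str = ""
    inventory: UnitInventory | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be trials x features")
        if self.X.shape[0] != len(self.tokens):
            raise ValueError("one token label per trial required")
        if self.X.shape[1] != self.samples_per_channel * len(self.channel_ids):
            raise ValueError("feature count != samples_per_channel * n_channels")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def token_ids(self) -> list[str]:
        if self.inventory is not None:
            return list(self.inventory.token_alphabet)
        return sorted(set(self.tokens))

    def channel_block(self, indices) -> np.ndarray:
        """Features restricted to the given channel indices (duplicates kept)."""
        s = self.samples_per_channel
        cols = np.concatenate([np.arange(i * s, (i + 1) * s) for i in indices])
        return self.X[:, cols]

    def token_means(self, X: np.ndarray | None = None) -> np.ndarray:
        """Token-mean patterns, ordered by ``token_ids``."""
        X = self.X if X is None else X
        tokens = np.asarray(self.tokens)
        return np.stack([X[tokens == t].mean(axis=0) for t in self.token_ids])


@dataclass
class RDM:
    """Token x token cross-validated dissimilarity for one electrode set.

    The diagonal holds cross-validated self-distances and is not interpreted.
    """

    tokens: list[str]
    D: np.ndarray
    n_folds: int = 5
    electrode_set: str = ""

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.tokens),) * 2:
            raise ValueError("D must be square over tokens")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.tokens, columns=self.tokens)


@dataclass
class SchemeModel:
    """Binary model RDM for a coding scheme: 0 within category, 1 between.

    Cells excluded from the comparison (e.g., same-position pairs in the
    identity model) are NaN.
    """

    scheme: str
    tokens: list[str]
    M: np.ndarray
    categories: dict[str, int] = field(default_factory=dict)


@dataclass
class ContrastResult:
    """Resampled within/between category similarity for one scheme and set.

    ``within_cell_z``/``between_cell_z`` hold the resample-averaged Fisher-z
    similarity of each token pair in the two cell sets; the rank-sum test
    compares these two sets of cells.  ``within_z``/``between_z`` hold the
    per-resample cell-set averages, used for the across-set Friedman test.
    """

    scheme: str
    electrode_set: str
    within_z: np.ndarray  # mean Fisher-z within-category similarity per resample
    between_z: np.ndarray
    within_cell_z: np.ndarray  # resample-averaged Fisher-z per within cell
    between_cell_z: np.ndarray
    statistic: float  # two-sided Wilcoxon rank-sum over cells, within vs between
    p_value: float

    @property
    def n_resamples(self) -> int:
        return len(self.within_z)

    @property
    def diff(self) -> np.ndarray:
        return self.within_z - self.between_z


def epoch_patterns(
    recording: NeuralRecording,
    stream: TokenStream,
    channel_set: list[str],
    window_s: tuple[float, float] | None = None,
    electrode_set: str = "",
    demean_epochs: bool = True,
) -> PatternSet:
    """One feature vector per non-probe token occurrence.

    The epoch window defaults to one SOA starting at token onset, half-open,
    giving ``floor(window * rate)`` samples per channel.  Probe tokens and
    occurrences extending past the recording are excluded.  Each channel's
    epoch mean is subtracted by default (baseline correction): 1/f background
    activity is correlated across neighboring epochs, and without this step
    tokens that frequently occur adjacently — in particular tokens of the same
    unit — inherit spurious similarity from shared slow noise.
    """
    if not channel_set:
        raise ValueError("channel_set must not be empty")
    sub = recording.pick(channel_set)
    w0, w1 = window_s if window_s is not None else (0.0, stream.soa_s)
    if not 0 <= w0 < w1:
        raise ValueError("window must satisfy 0 <= start < end")
    n_samp = int(np.floor((w1 - w0) * recording.rate_hz))
    if n_samp < 1:
        raise ValueError("window shorter than one sample")
    rows, labels = [], []
    for i, token in enumerate(stream.tokens):
        if stream.is_probe[i]:
            continue
        s0 = int(round((stream.onsets_s[i] + w0) * recording.rate_hz))
        if s0 + n_samp > sub.n_samples:
            continue
        epoch = sub.data[:, s0 : s0 + n_samp]
        if demean_epochs:
            epoch = epoch - epoch.mean(axis=1, keepdims=True)
        rows.append(epoch.reshape(-1))
        labels.append(token)
    return PatternSet(
        X=np.stack(rows),
        tokens=labels,
        channel_ids=list(channel_set),
        samples_per_channel=n_samp,
        electrode_set=electrode_set,
        window_s=(w0, w1),
        condition=stream.condition,
        inventory=stream.inventory,
    )


class PatternWhitener(BaseEstimator, TransformerMixin):
    """Center trials and whiten by a shrinkage-regularized noise covariance.

    The grand-average pattern across all tokens and trials (the nonspecific
    response) is subtracted from each trial; trials are then multiplied by the
    inverse matrix square root of a Ledoit-Wolf shrinkage covariance, whose
    shrinkage intensity is chosen analytically.  The noise covariance is
    estimated on residuals around the per-token means when token labels are
    supplied (so token-specific signal does not count as noise), else on
    grand-average residuals.

    Parameters
    ----------
    covariance : 'ledoitwolf' | 'identity' | ndarray
        Noise covariance estimator; 'identity' reduces to centering only.
    """

    def __init__(self, covariance="ledoitwolf"):
        self.covariance = covariance

    def fit(self, X: np.ndarray, y=None) -> "PatternWhitener":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("whitening needs a 2-D array with >= 2 trials")
        self.mean_ = X.mean(axis=0)
        if isinstance(self.covariance, str) and self.covariance == "identity":
            self.whitener_ = np.eye(X.shape[1])
            return self
        if y is not None:
            y = np.asarray(y)
            resid = X.copy()
            for t in np.unique(y):
                resid[y == t] -= X[y == t].mean(axis=0)
        else:
            resid = X - self.mean_
        if isinstance(self.covariance, str) and self.covariance == "ledoitwolf":
            cov = LedoitWolf(assume_centered=True).fit(resid).covariance_
        else:
            cov = np.asarray(self.covariance, dtype=float)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 1e-12, None)
        self.whitener_ = evecs @ np.diag(evals**-0.5) @ evecs.T
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.whitener_


def whiten_and_center(
    patterns: PatternSet, covariance="ledoitwolf"
) -> PatternSet:
    """Centered, spatially noise-whitened copy of a pattern set.

    The nonspecific response (grand-average feature vector) is subtracted from
    each trial; trials are then whitened across channels by the inverse square
    root of the channel x channel noise covariance, estimated with Ledoit-Wolf
    shrinkage from residuals around per-token means pooled over all epoch
    samples.  Spatial (channel-space) whitening is used because the noise that
    correlates features is shared across channels, not across time points
    within a channel.
    """
    T, C, S = patterns.n_trials, patterns.n_channels, patterns.samples_per_channel
    X = patterns.X
    centered = X - X.mean(axis=0)
    if isinstance(covariance, str) and covariance == "identity":
        return replace(patterns, X=centered)
    tokens = np.asarray(patterns.tokens)
    resid = X.copy()
    for t in np.unique(tokens):
        resid[tokens == t] -= X[tokens == t].mean(axis=0)
    obs = resid.reshape(T, C, S).transpose(0, 2, 1).reshape(T * S, C)
    if isinstance(covariance, str) and covariance == "ledoitwolf":
        cov = LedoitWolf(assume_centered=True).fit(obs).covariance_
    else:
        cov = np.asarray(covariance, dtype=float)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-12, None)
    W = evecs @ np.diag(evals**-0.5) @ evecs.T
    Y = np.einsum("dc,tcs->tds", W, centered.reshape(T, C, S)).reshape(T, C * S)
    return replace(patterns, X=Y)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


class CrossValidatedRDM(BaseEstimator):
    """Cross-validated correlation-distance RDM estimator.

    Trials are split into ``n_folds`` stratified by token.  Per fold,
    token-mean patterns are computed separately on the training and validation
    partitions and the distance between tokens a and b is

        d(a, b) = 1 - 0.5 * [corr(train_a, val_b) + corr(train_b, val_a)],

    averaged over folds.  Shared noise cancels in expectation, so identical
    true patterns give d ~ 0 even at finite SNR.
    """

    def __init__(self, n_folds: int = 5, random_state: int | None = 0):
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X: PatternSet, y=None) -> "CrossValidatedRDM":
        tokens = np.asarray(X.tokens)
        token_ids = X.token_ids
        for t in token_ids:
            count = int((tokens == t).sum())
            if count < self.n_folds:
                raise ValueError(
                    f"token {t!r} has {count} occurrences, fewer than "
                    f"n_folds={self.n_folds}"
                )
        n_tok = len(token_ids)
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        D = np.zeros((n_tok, n_tok))
        for train_idx, val_idx in skf.split(X.X, tokens):
            tr_tok, va_tok = tokens[train_idx], tokens[val_idx]
            train_means = np.stack(
                [X.X[train_idx][tr_tok == t].mean(axis=0) for t in token_ids]
            )
            val_means = np.stack(
                [X.X[val_idx][va_tok == t].mean(axis=0) for t in token_ids]
            )
            for a in range(n_tok):
                for b in range(a, n_tok):
                    c_ab = _pearson(train_means[a], val_means[b])
                    c_ba = _pearson(train_means[b], val_means[a])
                    d = 1.0 - 0.5 * (c_ab + c_ba)
                    D[a, b] += d
                    D[b, a] += d if a != b else 0.0
        D /= self.n_folds
        self.rdm_ = RDM(
            tokens=list(token_ids), D=D, n_folds=self.n_folds,
            electrode_set=X.electrode_set,
        )
        return self


def crossval_rdm(
    patterns: PatternSet, n_folds: int = 5, seed: int | None = 0
) -> RDM:
    """Cross-validated correlation-distance RDM (see :class:`CrossValidatedRDM`)."""
    return CrossValidatedRDM(n_folds=n_folds, random_state=seed).fit(patterns).rdm_


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Classical (Torgerson) scaling of a dissimilarity matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix and
    returns coordinates along the top components — equivalent to PCA of the
    implied feature configuration.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, D: np.ndarray, y=None) -> "ClassicalMDS":
        D = np.asarray(D, dtype=float)
        if not np.all(np.isfinite(D)):
            raise ValueError("dissimilarity matrix must be finite")
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = self.n_components
        pos = np.clip(evals[:k], 0.0, None)
        self.eigenvalues_ = evals
        self.embedding_ = evecs[:, :k] * np.sqrt(pos)
        return self

    def fit_transform(self, D: np.ndarray, y=None) -> np.ndarray:
        return self.fit(D).embedding_


def embed_2d(rdm: RDM) -> tuple[np.ndarray, np.ndarray]:
    """2-D classical-scaling embedding of an RDM: (coords, eigenvalues)."""
    mds = ClassicalMDS(n_components=2).fit(rdm.D)
    return mds.embedding_, mds.eigenvalues_


def _token_attrs(inventory: UnitInventory):
    tokens = list(inventory.token_alphabet)
    pos = inventory.position_of_token()
    unit = inventory.unit_of_token()
    return tokens, [pos[t] for t in tokens], [unit[t] for t in tokens]


def build_scheme_model(inventory: UnitInventory, scheme: str) -> SchemeModel:
    """Binary model RDM for 'tp', 'ordinal' or 'identity' coding.

    tp groups unit-initial (low-TP) tokens against later-position (high-TP)
    tokens; ordinal groups by position; identity groups by unit, with all
    same-position cells excluded (NaN) since those pairs never share a unit.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    tokens, pos, unit = _token_attrs(inventory)
    n = len(tokens)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if scheme == "tp":
                ci = 0 if pos[i] == 1 else 1
                cj = 0 if pos[j] == 1 else 1
                M[i, j] = 0.0 if ci == cj else 1.0
            elif scheme == "ordinal":
                M[i, j] = 0.0 if pos[i] == pos[j] else 1.0
            else:  # identity
                if pos[i] == pos[j]:
                    M[i, j] = np.nan
                else:
                    M[i, j] = 0.0 if unit[i] == unit[j] else 1.0
    if scheme == "tp":
        categories = {t: (0 if p == 1 else 1) for t, p in zip(tokens, pos)}
    elif scheme == "ordinal":
        categories = {t: p - 1 for t, p in zip(tokens, pos)}
    else:
        unit_index = {u: k for k, u in enumerate(inventory.unit_ids)}
        categories = {t: unit_index[u] for t, u in zip(tokens, unit)}
    return SchemeModel(scheme=scheme, tokens=tokens, M=M, categories=categories)


def model_rdm_comparison(
    rdm: RDM,
    models: list[SchemeModel],
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Spearman correlation of the RDM with each model RDM, permutation p.

    Only unmasked upper-triangle cells enter the correlation; the null
    distribution permutes token labels of the observed RDM.
    """
    rng = np.random.default_rng(seed)
    n = len(rdm.tokens)
    iu = np.triu_indices(n, k=1)
    rows = []
    for model in models:
        if model.tokens != rdm.tokens:
            raise ValueError("model and RDM token orders differ")
        mvec = model.M[iu]
        mask = np.isfinite(mvec)
        if mask.sum() < 10:
            raise ValueError("fewer than 10 unmasked cells")
        dvec = rdm.D[iu][mask]
        if np.ptp(dvec) == 0:
            raise ValueError("RDM is constant over unmasked cells; rho undefined")
        rho = stats.spearmanr(dvec, mvec[mask]).statistic
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            Dp = rdm.D[np.ix_(perm, perm)]
            dp = Dp[iu][mask]
            if np.ptp(dp) == 0:
                continue
            rho_p = stats.spearmanr(dp, mvec[mask]).statistic
            if abs(rho_p) >= abs(rho):
                exceed += 1
        rows.append(
            {
                "scheme": model.scheme,
                "rho": rho,
                "p_perm": (1.0 + exceed) / (1.0 + n_permutations),
            }
        )
    return pd.DataFrame(rows)


def contrast_cells(
    inventory: UnitInventory, scheme: str, include_third_third: bool = False
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(within, between) token-pair index sets for a category contrast.

    tp: within = low-TP (initial-initial) pairs; between = high-TP pairs
    (second-second plus second-third for triplets; second-second for pairs);
    third-third pairs enter only with ``include_third_third``.
    ordinal: same-position vs cross-position pairs.
    identity: same-unit cross-position vs cross-unit cross-position pairs.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    tokens, pos, unit = _token_attrs(inventory)
    L = inventory.unit_length
    within, between = [], []
    for i, j in combinations(range(len(tokens)), 2):
        pi, pj = pos[i], pos[j]
        if scheme == "tp":
            if pi == 1 and pj == 1:
                within.append((i, j))
            elif L == 2 and pi == 2 and pj == 2:
                between.append((i, j))
            elif L >= 3:
                ps = {pi, pj}
                if ps == {2} or ps == {2, 3}:
                    between.append((i, j))
                elif ps == {3} and include_third_third:
                    between.append((i, j))
        elif scheme == "ordinal":
            (within if pi == pj else between).append((i, j))
        else:  # identity: same-position pairs excluded entirely
            if pi == pj:
                continue
            (within if unit[i] == unit[j] else between).append((i, j))
    return within, between


def resampled_contrast(
    patterns: PatternSet,
    scheme: str,
    n_resamples: int = 200,
    seed: int | None = 0,
    include_third_third: bool = False,
) -> ContrastResult:
    """Channel-resampled within vs between category similarity contrast.

    Per resample, channels are drawn with replacement (same count), token-mean
    patterns are correlated pairwise (Pearson) and Fisher transformed.  Each
    token-pair cell's similarity is averaged over resamples — the resampling
    guards against any single channel driving the similarity — and the
    within-category cells are compared against the between-category cells
    with a two-sided Wilcoxon rank-sum test.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2 for the rank-sum test")
    if patterns.n_channels < 2:
        raise ValueError("need >= 2 channels to resample")
    if patterns.inventory is None:
        raise ValueError("contrast requires a pattern set with a unit inventory")
    rng = np.random.default_rng(seed)
    within_cells, between_cells = contrast_cells(
        patterns.inventory, scheme, include_third_third
    )
    w_i, w_j = zip(*within_cells)
    b_i, b_j = zip(*between_cells)
    s = patterns.samples_per_channel
    means_by_channel = patterns.token_means().reshape(
        len(patterns.token_ids), patterns.n_channels, s
    )
    within_z = np.empty(n_resamples)
    between_z = np.empty(n_resamples)
    w_cells = np.zeros(len(within_cells))
    b_cells = np.zeros(len(between_cells))
    for r in range(n_resamples):
        pick = rng.integers(0, patterns.n_channels, size=patterns.n_channels)
        tm = means_by_channel[:, pick, :].reshape(len(patterns.token_ids), -1)
        C = np.corrcoef(tm)
        Z = np.arctanh(np.clip(C, -1 + 1e-12, 1 - 1e-12))
        within_z[r] = Z[w_i, w_j].mean()
        between_z[r] = Z[b_i, b_j].mean()
        w_cells += Z[w_i, w_j]
        b_cells += Z[b_i, b_j]
    w_cells /= n_resamples
    b_cells /= n_resamples
    stat, p = stats.ranksums(w_cells, b_cells)
    return ContrastResult(
        scheme=scheme,
        electrode_set=patterns.electrode_set,
        within_z=within_z,
        between_z=between_z,
        within_cell_z=w_cells,
        between_cell_z=b_cells,
        statistic=float(stat),
        p_value=float(p),
    )


def friedman_across_sets(contrasts: list[ContrastResult]) -> dict:
    """Friedman test of the within-minus-between effect across electrode sets.

    Resample indices must be matched across sets.  Pairwise follow-up rank-sum
    tests are Bonferroni adjusted.  With only two sets a rank-sum test is
    reported instead (Friedman needs >= 3 groups).
    """
    if len(contrasts) < 2:
        raise ValueError("need >= 2 electrode sets")
    diffs = [c.diff for c in contrasts]
    n = {len(d) for d in diffs}
    if len(n) != 1:
        raise ValueError("electrode sets must share the resample count")
    labels = [c.electrode_set or f"set{i}" for i, c in enumerate(contrasts)]
    if len(contrasts) == 2:
        stat, p = stats.ranksums(diffs[0], diffs[1])
        return {
            "test": "ranksum",
            "note": "only two electrode sets; Friedman requires >= 3",
            "statistic": float(stat),
            "p_value": float(p),
            "pairwise": [],
        }
    chi2, p = stats.friedmanchisquare(*diffs)
    m = len(contrasts) * (len(contrasts) - 1) // 2
    pairwise = []
    for (i, a), (j, b) in combinations(enumerate(labels), 2):
        s, pr = stats.ranksums(diffs[i], diffs[j])
        pairwise.append(
            {
                "set_a": a,
                "set_b": b,
                "statistic": float(s),
                "p_bonferroni": float(min(1.0, pr * m)),
            }
        )
    return {
        "test": "friedman",
        "statistic": float(chi2),
        "p_value": float(p),
        "pairwise": pairwise,
    }
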
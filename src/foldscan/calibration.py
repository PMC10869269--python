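"""Score calibration: E-values from per-query Gumbel fits and a
match-probability model from two-gamma mixtures.

The highest local-alignment score of a query against unrelated sequences
follows an extreme-value (Gumbel) distribution whose location mu and scale
lambda depend on the query.  Calibration therefore (1) aligns queries
against shuffled copies of the database and fits Gumbel parameters by
maximum likelihood, (2) trains a small feed-forward regression from query
composition + length to (mu, lambda) so E-values need no per-query
shuffling at search time, and (3) optionally corrects reported E-values by
a power law estimated from the scrambled-search behavior.

Separately, the probability that a match with a given structural bit score
is a true positive is obtained by Bayes' rule from two-gamma mixture fits
to the score distributions of known true and false matches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import digamma, polygamma
from scipy.stats import gamma as gamma_dist

from .search import AlignmentParams, align_local
from .structure_io import DatabaseEntry
from .substitution import SubstitutionMatrix


class ConfigError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class GumbelParams:
    mu: float
    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel scale parameter lambda must be positive")


def fit_gumbel(scores, min_n: int = 30) -> GumbelParams:
    """Maximum-likelihood Gumbel (max-EVD) fit.

    Solves the profile likelihood equation for lambda by damped Newton
    iteration and recovers mu in closed form.  Converges to a gradient
    magnitude below 1e-10.
    """
    x = np.asarray(scores, dtype=np.float64)
    if len(x) < min_n:
        raise ConfigError(f"need at least {min_n} scores, got {len(x)}")
    sd = x.std()
    if sd < 1e-12:
        raise DegenerateFitError("all scores identical")
    xbar = x.mean()
    lam = np.pi / (np.sqrt(6.0) * sd)  # method-of-moments start
    shift = x.max()  # stabilize exp(-lam * x)
    for _ in range(200):
        w = np.exp(-lam * (x - shift))
        sw = w.sum()
        ew_x = (w * x).sum() / sw
        ew_x2 = (w * x * x).sum() / sw
        g = 1.0 / lam - xbar + ew_x
        if abs(g) < 1e-10:
            break
        gprime = -1.0 / lam ** 2 - (ew_x2 - ew_x ** 2)
        step = g / gprime
        new_lam = lam - step
        damping = 1.0
        while new_lam <= 0 and damping > 1e-8:
            damping /= 2.0
            new_lam = lam - damping * step
        lam = new_lam
    w = np.exp(-lam * (x - shift))
    mu = shift - np.log(w.mean()) / lam
    return GumbelParams(mu=float(mu), lam=float(lam))


# ---------------------------------------------------------------------------
# calibration table from shuffled-database searches
# ---------------------------------------------------------------------------

def shuffle_entry(entry: DatabaseEntry, rng: np.random.Generator) -> DatabaseEntry:
    """Shuffle both sequences of an entry with one permutation, preserving
    length and composition (coordinates are irrelevant for calibration)."""
    perm = rng.permutation(len(entry))
    return DatabaseEntry(
        entry_id=entry.entry_id + "_shuf",
        aa_seq="".join(entry.aa_seq[p] for p in perm),
        tdi_seq="".join(entry.tdi_seq[p] for p in perm),
        ca_coords=entry.ca_coords[perm],
    )


def query_features(entry: DatabaseEntry, letters: str) -> np.ndarray:
    """22 inputs: state-composition fractions (20), length, log(length+1)."""
    L = len(entry)
    comp = np.array([entry.tdi_seq.count(ch) for ch in letters], dtype=np.float64)
    comp /= max(L, 1)
    return np.concatenate([comp, [float(L), np.log(L + 1.0)]])


def build_calibration_table(queries: list[DatabaseEntry],
                            target_db: list[DatabaseEntry],
                            tdi_matrix: SubstitutionMatrix,
                            n_align: int = 1000,
                            seed: int = 0,
                            aln_params: AlignmentParams | None = None
                            ) -> list[dict]:
    """Per-query Gumbel parameters from alignments against shuffled targets.

    Each of ``n_align`` alignments (reverse correction off — the null model
    must see raw forward scores) is against a freshly permuted copy of a
    target, cycling through the database.  Returns one row per query with
    its feature vector and fitted (mu, lambda).
    """
    if n_align < 30:
        raise ConfigError("n_align must be at least 30 for a stable Gumbel fit")
    if not target_db:
        raise ValueError("empty target database")
    rng = np.random.default_rng(seed)
    params = replace(aln_params or AlignmentParams(), use_reverse_correction=False)
    rows = []
    for query in queries:
        scores = np.empty(n_align)
        for a in range(n_align):
            target = shuffle_entry(target_db[a % len(target_db)], rng)
            scores[a] = align_local(query, target, tdi_matrix, params=params).bit_score
        fit = fit_gumbel(scores)
        rows.append({"query_id": query.entry_id,
                     "features": query_features(query, tdi_matrix.letters),
                     "mu": fit.mu, "lam": fit.lam})
    return rows


# ---------------------------------------------------------------------------
# the (mu, lambda) regression network
# ---------------------------------------------------------------------------

@dataclass
class EvalueModel:
    """Feed-forward (mu, lambda) predictor plus the E-value correction.

    22 inputs -> two 32-unit ReLU layers -> 2 linear outputs, trained by
    Adam at learning rate 1e-3 with a 90/10 validation split and early
    stopping.  Inputs and targets are z-scored; predicted lambda is clamped
    positive.
    """

    net: object
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    letters: str
    correction_exponent: float = 0.32
    correction_scale: float = 1.0
    training_seed: int = 0

    def predict(self, features: np.ndarray) -> tuple[float, float]:
        x = (np.atleast_2d(features) - self.x_mean) / self.x_std
        y = np.atleast_2d(self.net.predict(x)) * self.y_std + self.y_mean
        mu, lam = float(y[0, 0]), float(y[0, 1])
        return mu, max(lam, 1e-6)

    def save(self, path) -> None:
        import json
        from pathlib import Path
        payload = {
            "coefs": [np.asarray(c).tolist() for c in self.net.coefs_],
            "intercepts": [np.asarray(b).tolist() for b in self.net.intercepts_],
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(), "y_std": self.y_std.tolist(),
            "letters": self.letters,
            "correction_exponent": self.correction_exponent,
            "correction_scale": self.correction_scale,
            "training_seed": self.training_seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "EvalueModel":
        import json
        from pathlib import Path
        d = json.loads(Path(path).read_text())
        net = _MLPForward([np.array(c) for c in d["coefs"]],
                          [np.array(b) for b in d["intercepts"]])
        return cls(net=net, x_mean=np.array(d["x_mean"]), x_std=np.array(d["x_std"]),
                   y_mean=np.array(d["y_mean"]), y_std=np.array(d["y_std"]),
                   letters=d["letters"],
                   correction_exponent=d["correction_exponent"],
                   correction_scale=d["correction_scale"],
                   training_seed=d["training_seed"])


class _MLPForward:
    """Forward-only ReLU network mirroring a fitted sklearn regressor."""

    def __init__(self, coefs, intercepts):
        self.coefs_ = coefs
        self.intercepts_ = intercepts

    def predict(self, X):
        h = np.atleast_2d(X)
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.coefs_[-1] + self.intercepts_[-1]


def train_evalue_net(table: list[dict], seed: int = 0, min_rows: int = 100,
                     correction_exponent: float = 0.32,
                     letters: str | None = None,
                     max_iter: int = 2000) -> EvalueModel:
    """MSE regression of (mu, lambda) on the query features."""
    from sklearn.neural_network import MLPRegressor

    if len(table) < min_rows:
        raise ConfigError(f"need at least {min_rows} calibration rows, got {len(table)}")
    X = np.array([row["features"] for row in table])
    Y = np.array([[row["mu"], row["lam"]] for row in table])
    bad = ~np.isfinite(Y).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite calibration targets in rows {np.nonzero(bad)[0].tolist()}")
    # canonicalize then reshuffle by seed so the fit (incl. the validation
    # split) is invariant to the caller's row order
    order = np.lexsort(np.vstack([Y.T, X.T]))
    order = order[np.random.default_rng(seed).permutation(len(order))]
    X, Y = X[order], Y[order]
    x_mean, x_std = X.mean(axis=0), X.std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    y_mean, y_std = Y.mean(axis=0), Y.std(axis=0)
    y_std[y_std < 1e-12] = 1.0
    net = MLPRegressor(hidden_layer_sizes=(32, 32), activation="relu",
                       solver="adam", learning_rate_init=1e-3,
                       early_stopping=True, validation_fraction=0.1,
                       n_iter_no_change=25, max_iter=max_iter,
                       random_state=seed)
    net.fit((X - x_mean) / x_std, (Y - y_mean) / y_std)
    if letters is None:
        letters = "ABCDEFGHIJKLMNOPQRST"
    return EvalueModel(net=net, x_mean=x_mean, x_std=x_std, y_mean=y_mean,
                       y_std=y_std, letters=letters,
                       correction_exponent=correction_exponent,
                       training_seed=seed)


def evalue_from_params(mu: float, lam: float, bit_score: float, db_size: int,
                       correction_exponent: float = 1.0,
                       correction_scale: float = 1.0) -> float:
    """E = scale * (db_size * exp(-lambda (s - mu))) ** exponent."""
    e_raw = db_size * np.exp(-lam * (bit_score - mu))
    if e_raw <= 0:
        return 0.0
    return float(correction_scale * e_raw ** correction_exponent)


def evalue(model: EvalueModel, query_feats: np.ndarray, bit_score: float,
           db_size: int) -> float:
    mu, lam = model.predict(query_feats)
    return evalue_from_params(mu, lam, bit_score, db_size,
                              model.correction_exponent, model.correction_scale)


def fit_evalue_correction(raw_evalues_per_query: list[np.ndarray],
                          thresholds=(0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
                          ) -> tuple[float, float]:
    """Log-log regression of mean false-positive counts on raw E-values.

    Given, per scrambled query, the raw (uncorrected) E-values of all its
    hits, fit ``log(mean count at threshold) = log(scale) + exponent *
    log(threshold)``.  Reporting ``scale * E_raw ** exponent`` then makes
    the expected false-positive count track the reported E-value.  The
    power-law part matches the literature's slope correction; the scale
    absorbs any offset of the shuffled-sequence null against real targets.

    Thresholds where the count saturates toward the database size (above a
    quarter of it) carry no calibration signal and are excluded, as are
    thresholds with zero observed counts.
    """
    n_q = len(raw_evalues_per_query)
    if n_q == 0:
        raise ValueError("no scrambled-query results")
    capacity = float(np.mean([len(ev) for ev in raw_evalues_per_query]))
    xs, ys = [], []
    for thr in thresholds:
        mean_fp = sum(float((ev <= thr).sum()) for ev in raw_evalues_per_query) / n_q
        if 0.0 < mean_fp <= 0.25 * capacity:
            xs.append(np.log(thr))
            ys.append(np.log(mean_fp))
    if len(xs) < 2:
        return 1.0, 1.0
    slope, intercept = np.polyfit(xs, ys, 1)
    exponent = float(np.clip(slope, 0.05, 2.0))
    scale = float(np.clip(np.exp(intercept), 1e-6, 1e6))
    return exponent, scale


def estimate_correction_exponent(raw_evalues_per_query: list[np.ndarray],
                                 thresholds=(0.1, 0.3, 1.0, 3.0, 10.0)) -> float:
    """Slope-only variant of :func:`fit_evalue_correction`."""
    return fit_evalue_correction(raw_evalues_per_query, thresholds)[0]


# ---------------------------------------------------------------------------
# two-gamma mixtures and the TP probability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaMixture:
    """weight * Gamma(shape1, rate1) + (1 - weight) * Gamma(shape2, rate2)"""

    weight: float
    shape1: float
    rate1: float
    shape2: float
    rate2: float

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return (self.weight * gamma_dist.pdf(x, self.shape1, scale=1.0 / self.rate1)
                + (1.0 - self.weight) * gamma_dist.pdf(x, self.shape2, scale=1.0 / self.rate2))

    def mean(self) -> float:
        return self.weight * self.shape1 / self.rate1 + \
            (1.0 - self.weight) * self.shape2 / self.rate2


@dataclass(frozen=True)
class GammaMixturePair:
    tp: GammaMixture
    fp: GammaMixture
    prior_tp: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_tp <= 1.0:
            raise ValueError("prior_tp must be in [0, 1]")


def _gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE via Newton on the shape equation."""
    sw = w.sum()
    m = (w * x).sum() / sw
    mlog = (w * np.log(x)).sum() / sw
    s = np.log(m) - mlog
    s = max(s, 1e-8)
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        f = np.log(a) - digamma(a) - s
        fp_ = 1.0 / a - polygamma(1, a)
        step = f / fp_
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12:
            a = a_new
            break
        a = a_new
    a = float(np.clip(a, 1e-3, 1e4))
    return a, a / m


def _fit_two_gamma(x: np.ndarray, rng: np.random.Generator,
                   tol: float = 1e-8, max_iter: int = 500) -> tuple[GammaMixture, float]:
    # init: random quantile split
    split = rng.uniform(0.3, 0.7)
    q = np.quantile(x, split)
    labels = x > q
    if labels.all() or (~labels).all():
        labels = x > np.median(x)
    comps = []
    for mask in (~labels, labels):
        xm = x[mask] if mask.any() else x
        a, b = _gamma_mle(xm, np.ones(len(xm)))
        comps.append((a, b))
    weight = float((~labels).mean())
    weight = min(max(weight, 0.05), 0.95)
    prev_ll = -np.inf
    for _ in range(max_iter):
        p1 = weight * gamma_dist.pdf(x, comps[0][0], scale=1.0 / comps[0][1])
        p2 = (1 - weight) * gamma_dist.pdf(x, comps[1][0], scale=1.0 / comps[1][1])
        total = p1 + p2 + 1e-300
        ll = float(np.log(total).sum())
        r1 = p1 / total
        weight = float(np.clip(r1.mean(), 1e-4, 1 - 1e-4))
        comps = [_gamma_mle(x, r1 + 1e-12), _gamma_mle(x, 1 - r1 + 1e-12)]
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    mix = GammaMixture(weight, comps[0][0], comps[0][1], comps[1][0], comps[1][1])
    return mix, prev_ll


def fit_gamma_mixture(scores, seed: int = 0, n_restarts: int = 5) -> GammaMixture:
    """Best-of-restarts EM fit of a two-component gamma mixture."""
    x = np.asarray(scores, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("no scores to fit")
    if (x <= 0).any():
        raise ValueError("gamma mixture requires strictly positive scores")
    best_mix, best_ll = None, -np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        mix, ll = _fit_two_gamma(x, rng)
        if ll > best_ll:
            best_mix, best_ll = mix, ll
    return best_mix


def fit_tp_fp_mixtures(scores_tp, scores_fp, prior_tp: float,
                       seed: int = 0) -> GammaMixturePair:
    """Fit the class-conditional score densities for the TP probability."""
    return GammaMixturePair(tp=fit_gamma_mixture(scores_tp, seed=seed),
                            fp=fit_gamma_mixture(scores_fp, seed=seed + 1000),
                            prior_tp=prior_tp)


def p_tp(score, mixtures: GammaMixturePair) -> float:
    """Posterior probability that a match with this score is a true match."""
    num = mixtures.prior_tp * mixtures.tp.pdf(score)
    den = num + (1.0 - mixtures.prior_tp) * mixtures.fp.pdf(score)
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))
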
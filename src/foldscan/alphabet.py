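"""The 20-state structural alphabet: training and encoding.

States are learned with a vector-quantized autoencoder trained on pairs of
interaction descriptors from structurally aligned residues: the encoder
embeds the 10-feature descriptor of one residue into a 2D latent space,
the embedding snaps to the nearest of 20 centroids, and the decoder must
predict the descriptor distribution of the *aligned* residue from the
centroid alone.  Because reconstruction targets the evolutionary partner
rather than the input, the discrete states end up maximally conserved
between homologs, which is what makes them useful substitution-matrix
symbols.

After training only the encoder, the feature scaler and the centroids are
needed to turn a structure into a state string; residues without a valid
descriptor (chain termini, missing atoms, absent partner) receive 'X'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .chain import Chain
from .geometry import N_FEATURES, VirtualCenterParams, chain_descriptors

#: state letters in centroid index order; 'X' reserved for unknown
STATE_LETTERS = "ABCDEFGHIJKLMNOPQRST"
UNKNOWN = "X"


class ConfigError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PairFilterParams:
    """Filters applied to structurally aligned residue pairs before training."""

    min_tm: float = 0.6
    max_ca_dist: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.min_tm <= 1:
            raise ValueError("min_tm must be in (0, 1]")


@dataclass(frozen=True)
class VqvaeConfig:
    n_states: int = 20
    latent_dim: int = 2
    hidden_dim: int = 10
    hidden_layers: int = 2
    commitment_cost: float = 0.25
    batch_size: int = 512
    learning_rate: float = 1e-3
    epochs: int = 4
    n_restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_states", "latent_dim", "hidden_dim", "hidden_layers",
                     "batch_size", "epochs", "n_restarts"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class Alphabet3Di:
    """Trained encoder + centroids: everything needed to encode structures."""

    encoder: nn.MLP
    centroids: np.ndarray  # (n_states, latent_dim)
    feat_mean: np.ndarray
    feat_std: np.ndarray
    letters: str = STATE_LETTERS
    config: VqvaeConfig = field(default_factory=VqvaeConfig)

    @property
    def n_states(self) -> int:
        return len(self.centroids)

    def embed(self, features: np.ndarray) -> np.ndarray:
        """Latent embedding of raw (unstandardized) descriptors."""
        x = (np.atleast_2d(features) - self.feat_mean) / self.feat_std
        return self.encoder.forward(x, train=False)

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Nearest-centroid state index for each descriptor row."""
        return nearest_centroid(self.embed(features), self.centroids)

    def inference_param_count(self) -> int:
        """Fully connected encoder parameters plus centroid coordinates
        (batch-normalization parameters excluded)."""
        return self.encoder.linear_param_count() + self.centroids.size

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        layers = []
        for layer in self.encoder.layers:
            if isinstance(layer, nn.Linear):
                layers.append({"kind": "linear", "W": layer.W.tolist(),
                               "b": layer.b.tolist()})
            elif isinstance(layer, nn.BatchNorm):
                layers.append({"kind": "batchnorm", "gamma": layer.gamma.tolist(),
                               "beta": layer.beta.tolist(),
                               "running_mean": layer.running_mean.tolist(),
                               "running_var": layer.running_var.tolist()})
            else:
                layers.append({"kind": "relu"})
        return {
            "layers": layers,
            "centroids": self.centroids.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_std": self.feat_std.tolist(),
            "letters": self.letters,
            "config": self.config.__dict__,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Alphabet3Di":
        layers: list[nn.Layer] = []
        rng = np.random.default_rng(0)
        for spec in d["layers"]:
            if spec["kind"] == "linear":
                W = np.array(spec["W"])
                lin = nn.Linear(W.shape[1], W.shape[0], rng)
                lin.W = W
                lin.b = np.array(spec["b"])
                lin.dW = np.zeros_like(lin.W)
                lin.db = np.zeros_like(lin.b)
                layers.append(lin)
            elif spec["kind"] == "batchnorm":
                bnorm = nn.BatchNorm(len(spec["gamma"]))
                bnorm.gamma = np.array(spec["gamma"])
                bnorm.beta = np.array(spec["beta"])
                bnorm.running_mean = np.array(spec["running_mean"])
                bnorm.running_var = np.array(spec["running_var"])
                layers.append(bnorm)
            else:
                layers.append(nn.ReLU())
        return cls(
            encoder=nn.MLP(layers),
            centroids=np.array(d["centroids"]),
            feat_mean=np.array(d["feat_mean"]),
            feat_std=np.array(d["feat_std"]),
            letters=d["letters"],
            config=VqvaeConfig(**d["config"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "Alphabet3Di":
        return cls.from_dict(json.loads(Path(path).read_text()))


def nearest_centroid(latent: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((latent[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# training data
# ---------------------------------------------------------------------------

def build_training_pairs(aligned_pairs, filters: PairFilterParams = PairFilterParams(),
                         vc_params: VirtualCenterParams = VirtualCenterParams()
                         ) -> np.ndarray:
    """Descriptor pairs (x, y) from structurally aligned residues.

    ``aligned_pairs`` is a list of ``(chain_a, chain_b, alignment, tm_score)``
    where the alignment is a list of 0-based residue index pairs and the two
    chains are assumed superposed (CA distances are measured directly).
    Alignments below the TM threshold contribute nothing; residue pairs
    farther than the CA cutoff are dropped; both residues need valid
    descriptors.  Output is symmetrized: (x, y) and (y, x) are both emitted.
    Returns an (N, 2, 10) array.
    """
    out = []
    for chain_a, chain_b, alignment, tm_score in aligned_pairs:
        if tm_score < filters.min_tm:
            continue
        feats_a, valid_a, _ = chain_descriptors(chain_a, vc_params)
        feats_b, valid_b, _ = chain_descriptors(chain_b, vc_params)
        for i, j in alignment:
            if not (valid_a[i] and valid_b[j]):
                continue
            if np.linalg.norm(chain_a.ca[i] - chain_b.ca[j]) > filters.max_ca_dist:
                continue
            out.append((feats_a[i], feats_b[j]))
            out.append((feats_b[j], feats_a[i]))
    if not out:
        return np.zeros((0, 2, N_FEATURES))
    return np.array(out)


# ---------------------------------------------------------------------------
# VQ-VAE training
# ---------------------------------------------------------------------------

_LOG_2PI = np.log(2.0 * np.pi)


def _gaussian_nll(y: np.ndarray, mu: np.ndarray, logvar: np.ndarray) -> float:
    return float(0.5 * np.mean(np.sum(logvar + (y - mu) ** 2 / np.exp(logvar)
                                      + _LOG_2PI, axis=1)))


def train_vqvae(pairs: np.ndarray, config: VqvaeConfig = VqvaeConfig(),
                ) -> tuple[Alphabet3Di, nn.MLP, list[dict]]:
    """Train one alphabet candidate from descriptor pairs.

    The loss is the negative log-likelihood of the partner descriptor under
    the decoder's diagonal Gaussian, plus the codebook term pulling centroids
    toward encoder outputs and the commitment term (weight
    ``commitment_cost``) pulling encoder outputs toward their centroid.
    Gradients flow through the quantization by the straight-through
    estimator; codebook entries unused for a full epoch are reseeded from a
    random encoder output.  Deterministic given ``config.seed``.

    Returns ``(alphabet, decoder, per-epoch training log)``.
    """
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 3 or pairs.shape[1] != 2:
        raise ValueError("pairs must have shape (N, 2, n_features)")
    n = len(pairs)
    if n < config.batch_size:
        raise ConfigError(f"{n} pairs < batch_size {config.batch_size}")
    rng = np.random.default_rng(config.seed)
    X = pairs[:, 0, :]
    Y = pairs[:, 1, :]
    feat_mean = X.mean(axis=0)
    feat_std = X.std(axis=0)
    feat_std[feat_std < 1e-8] = 1.0
    Xs = (X - feat_mean) / feat_std
    Ys = (Y - feat_mean) / feat_std

    d_in = X.shape[1]
    enc_dims = [d_in] + [config.hidden_dim] * config.hidden_layers + [config.latent_dim]
    dec_dims = [config.latent_dim] + [config.hidden_dim] * config.hidden_layers + [2 * d_in]
    encoder = nn.mlp(enc_dims, rng)
    decoder = nn.mlp(dec_dims, rng)
    # seed centroids from initial encoder outputs so codes start occupied
    warm = encoder.forward(Xs[rng.choice(n, size=min(n, 2048), replace=False)], train=True)
    centroids = warm[rng.choice(len(warm), size=config.n_states, replace=False)].copy()
    d_cent = np.zeros_like(centroids)
    opt = nn.Adam(encoder.params() + decoder.params() + [centroids],
                  encoder.grads() + decoder.grads() + [d_cent],
                  lr=config.learning_rate)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        used = np.zeros(config.n_states, dtype=bool)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = Xs[idx], Ys[idx]
            B = len(x)
            encoder.zero_grad()
            decoder.zero_grad()
            d_cent[...] = 0.0

            z_e = encoder.forward(x, train=True)
            assign = nearest_centroid(z_e, centroids)
            used[np.unique(assign)] = True
            z_q = centroids[assign]
            out = decoder.forward(z_q, train=True)  # straight-through: grads -> z_e
            mu, logvar = out[:, :d_in], out[:, d_in:]
            logvar = np.clip(logvar, -10.0, 10.0)
            var = np.exp(logvar)

            nll = _gaussian_nll(y, mu, logvar)
            codebook = float(np.mean(np.sum((z_q - z_e) ** 2, axis=1)))
            loss = nll + codebook + config.commitment_cost * codebook
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1

            dout = np.empty_like(out)
            dout[:, :d_in] = (mu - y) / var / B
            dout[:, d_in:] = 0.5 * (1.0 - (y - mu) ** 2 / var) / B
            dz_q = decoder.backward(dout)
            # straight-through to the encoder, plus the commitment pull
            dz_e = dz_q + config.commitment_cost * 2.0 * (z_e - z_q) / B
            encoder.backward(dz_e)
            # codebook term moves only the centroids
            np.add.at(d_cent, assign, 2.0 * (z_q - z_e) / B)
            opt.step()
        dead = np.nonzero(~used)[0]
        for k in dead:  # reseed dead codes from live encoder outputs
            centroids[k] = encoder.forward(Xs[rng.integers(n)][None], train=False)[0]
        log.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1),
                    "dead_codes": len(dead)})
    alphabet = Alphabet3Di(encoder=encoder, centroids=centroids,
                           feat_mean=feat_mean, feat_std=feat_std,
                           letters=STATE_LETTERS[:config.n_states], config=config)
    return alphabet, decoder, log


def train_restarts(pairs: np.ndarray, config: VqvaeConfig) -> list[Alphabet3Di]:
    """Train ``config.n_restarts`` candidates from consecutive seeds."""
    return [train_vqvae(pairs, replace(config, seed=config.seed + r))[0]
            for r in range(config.n_restarts)]


@dataclass
class ValidationBenchmark:
    """Scores an alphabet candidate on a labeled validation set.

    ``evaluate(alphabet)`` returns the ROC1 AUC per level; ``reference_auc``
    holds the structure-superposition reference AUC for the same levels.
    """

    evaluate: "callable"
    reference_auc: dict[str, float]


def select_best_alphabet(candidates: list[Alphabet3Di],
                         benchmark: ValidationBenchmark) -> Alphabet3Di:
    """Pick the candidate maximizing the summed AUC ratio over the three
    homology levels; earlier candidates win ties."""
    if not candidates:
        raise ValueError("no candidates")
    best, best_score = None, -np.inf
    for cand in candidates:
        aucs = benchmark.evaluate(cand)
        score = sum(aucs[level] / benchmark.reference_auc[level]
                    for level in benchmark.reference_auc)
        if score > best_score + 1e-12:
            best, best_score = cand, score
    return best


def encode_structure(chain: Chain, alphabet: Alphabet3Di,
                     vc_params: VirtualCenterParams = VirtualCenterParams()) -> str:
    """State string for one chain; invalid positions become 'X'."""
    features, valid, _ = chain_descriptors(chain, vc_params)
    letters = [UNKNOWN] * len(chain)
    if valid.any():
        states = alphabet.assign(features[valid])
        for pos, state in zip(np.nonzero(valid)[0], states):
            letters[pos] = alphabet.letters[state]
    return "".join(letters)
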
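"""Adversarial conditional variational autoencoder for multi-source
expression data.

The generative story: a sample's log2(CPM+1) profile ``x`` is encoded into a
diagonal-Gaussian posterior ``Q(z|x) = N(mu, diag(exp(logvar)))`` over a
low-dimensional latent space with a standard-normal prior. The decoder
receives a draw ``z`` together with a one-hot vector ``s`` identifying the
sample's dataset of origin and reconstructs the profile, so origin-specific
"style" is supplied by ``s`` rather than stored in ``z``. An adversary — a
softmax classifier on ``z`` — tries to predict the origin; the encoder is
trained to defeat it. At equilibrium the embedding carries the biology but
not the origin, and decoding with a *different* ``s`` projects a sample into
another dataset's style (e.g., renders a cell line as if it were a clinical
tumor).

Losses (per batch):

    recon    = mean_{i,g} (x_ig - xhat_ig)^2          (unit-variance Gaussian NLL
                                                       per element, up to constants)
    kl       = mean_i 0.5 sum_d (mu^2 + e^logvar - 1 - logvar)
    adv_nll  = mean_i -log p(s_i | z_i)
    vae      = recon + w_kl * kl
    joint    = vae - lambda_adv * adv_nll

The joint objective is a minimax: the VAE minimises ``joint`` while the
adversary minimises ``adv_nll`` on its own parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import (
    EPS_PROB,
    Adam,
    Dense,
    clamp_logvar,
    dense_stack,
    nll_from_logits,
)

__all__ = [
    "BatchVAE",
    "LossComponents",
    "gaussian_kl",
    "vae_loss",
    "adversary_loss",
    "joint_loss",
]


@dataclass
class LossComponents:
    """The terms of the adversarial VAE objective for one batch/epoch."""

    recon: float
    kl: float
    w_kl: float
    adv_nll: float
    lambda_adv: float

    @property
    def loss_vae(self) -> float:
        return self.recon + self.w_kl * self.kl

    @property
    def loss_joint(self) -> float:
        return self.loss_vae - self.lambda_adv * self.adv_nll

    def as_dict(self) -> dict:
        return {
            "recon": self.recon,
            "kl": self.kl,
            "adv_nll": self.adv_nll,
            "loss_vae": self.loss_vae,
            "loss_joint": self.loss_joint,
        }


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL(N(mu, diag(e^logvar)) || N(0, I)), averaged over rows.

    Per sample: ``0.5 * sum_d (mu_d^2 + exp(logvar_d) - 1 - logvar_d)``.
    """
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    per_sample = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    return float(per_sample.mean())


def vae_loss(x, x_hat, mu, logvar, w_kl):
    """Reconstruction + weighted-KL terms; returns ``(recon, kl, loss_vae)``.

    Reconstruction is the Gaussian unit-variance negative log-likelihood up
    to constants: squared error averaged over all elements (batch x genes),
    which keeps it on a scale commensurate with the adversarial term so the
    printed loss weights behave as intended.
    """
    x = np.atleast_2d(x)
    x_hat = np.atleast_2d(x_hat)
    recon = float(np.mean((x - x_hat) ** 2))
    kl = gaussian_kl(mu, logvar)
    return recon, kl, recon + w_kl * kl


def adversary_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true source under ``probs``.

    ``labels`` are integer class indices (or a one-hot matrix). Zero
    probabilities are clamped at 1e-12 before the log.
    """
    probs = np.atleast_2d(probs)
    labels = np.asarray(labels)
    if labels.ndim == 2:  # one-hot
        labels = labels.argmax(axis=1)
    p_true = np.clip(probs[np.arange(probs.shape[0]), labels], EPS_PROB, None)
    return float(-np.log(p_true).mean())


def joint_loss(loss_vae: float, adv_nll: float, lambda_adv: float) -> float:
    """The minimax objective ``loss_vae - lambda_adv * adv_nll``."""
    return loss_vae - lambda_adv * adv_nll


def _as_matrix(X) -> np.ndarray:
    """Accept ndarray or AnnData; return a float (n_samples, n_genes) array."""
    if hasattr(X, "X"):  # AnnData
        X = X.X
    X = np.asarray(X, dtype=float)
    return np.atleast_2d(X)


def _validate_one_hot(S: np.ndarray, k: int) -> None:
    S = np.atleast_2d(S)
    if S.shape[1] != k:
        raise ValueError(f"one-hot width {S.shape[1]} != number of sources {k}")
    ok = np.all(np.isin(S, (0.0, 1.0))) and np.all(S.sum(axis=1) == 1)
    if not ok:
        raise ValueError("source matrix rows must be one-hot (single 1, rest 0)")


class BatchVAE(BaseEstimator, TransformerMixin):
    """Adversarial conditional VAE that strips dataset-of-origin effects.

    Fits on a normalized (samples x genes) matrix with a categorical source
    label per sample. ``transform`` returns the posterior-mean embedding;
    ``project`` decodes samples as if they originated from a chosen source.

    Parameters
    ----------
    latent_dim : width of the latent space (linear mu/logvar heads sit on
        the last encoder layer).
    encoder_hidden, decoder_hidden : hidden widths; the decoder expands back
        toward the gene dimension and its input is ``z`` concatenated with
        the one-hot source vector.
    adversary_hidden : hidden widths of the source discriminator; its output
        layer has one node per source with softmax activation.
    w_kl : weight of the KL regularizer in the VAE loss.
    lambda_adv : weight of the adversarial term in the joint loss.
    batch_size, learning_rate, epochs : Adam minibatch settings.
    adversarial_mode : "alternating" (adversary step(s), then VAE step, per
        minibatch, each with its own Adam) or "gradient_reversal" (single
        optimizer; the encoder receives the adversary's input gradient
        reversed and scaled by lambda_adv).
    adversary_steps : adversary updates per VAE update in alternating mode;
        keeping the discriminator close to optimal sharpens the invariance
        signal the encoder receives.
    stratify_batches : draw minibatches with per-source proportions matching
        the full data (useful when sources are very imbalanced).
    grad_clip : global L2-norm bound on each update's gradients (0 or None
        disables); keeps the minimax optimization from diverging when the
        encoder chases extreme embeddings to defeat the adversary.
    random_state : seed for weight init, shuffling, and latent sampling.

    Attributes
    ----------
    sources_ : ordered source names (sorted unique labels seen in fit).
    gene_ids_ : gene names when fitted from AnnData, else None.
    history_ : per-epoch list of loss/accuracy records.
    """

    def __init__(
        self,
        latent_dim: int = 64,
        encoder_hidden: tuple = (256, 128, 64),
        decoder_hidden: tuple = (64, 128, 256),
        adversary_hidden: tuple = (64, 32),
        w_kl: float = 1.1e-5,
        lambda_adv: float = 0.11,
        learning_rate: float = 1e-3,
        batch_size: int = 1600,
        epochs: int = 300,
        adversarial_mode: str = "alternating",
        adversary_steps: int = 1,
        stratify_batches: bool = False,
        grad_clip: float = 10.0,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.encoder_hidden = encoder_hidden
        self.decoder_hidden = decoder_hidden
        self.adversary_hidden = adversary_hidden
        self.w_kl = w_kl
        self.lambda_adv = lambda_adv
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.adversarial_mode = adversarial_mode
        self.adversary_steps = adversary_steps
        self.stratify_batches = stratify_batches
        self.grad_clip = grad_clip
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    # construction

    def _init_networks(self, n_genes: int, n_sources: int, rng: np.random.Generator):
        if n_sources < 2:
            raise ValueError(
                "at least 2 sources are required (the adversary is undefined "
                f"for a single source); got {n_sources}"
            )
        enc_sizes = [n_genes, *self.encoder_hidden]
        self.encoder_ = dense_stack(enc_sizes, rng, final_act=None)
        # trunk ends in an activation so the heads see SELU features
        from ._nn import SELU

        self.encoder_.layers.append(SELU())
        self.mu_head_ = Dense(self.encoder_hidden[-1], self.latent_dim, rng)
        self.logvar_head_ = Dense(self.encoder_hidden[-1], self.latent_dim, rng)
        from ._nn import ReLU

        dec_sizes = [self.latent_dim + n_sources, *self.decoder_hidden, n_genes]
        self.decoder_ = dense_stack(dec_sizes, rng, final_act=ReLU)
        adv_sizes = [self.latent_dim, *self.adversary_hidden, n_sources]
        self.adversary_ = dense_stack(adv_sizes, rng, final_act=None)
        self.n_genes_ = n_genes

    # ------------------------------------------------------------------ #
    # forward passes

    def encode(self, X):
        """Posterior parameters ``(mu, logvar)`` for each row of ``X``."""
        check_is_fitted(self, "encoder_")
        X = _as_matrix(X)
        if X.shape[1] != self.n_genes_:
            raise ValueError(
                f"input has {X.shape[1]} genes, model expects {self.n_genes_}"
            )
        h = self.encoder_.forward(X)
        mu = self.mu_head_.forward(h)
        logvar, _ = clamp_logvar(self.logvar_head_.forward(h))
        return mu, logvar

    def reparameterize(self, mu, logvar, rng: np.random.Generator):
        """Draw ``z = mu + exp(logvar/2) * eps`` with ``eps ~ N(0, I)``."""
        eps = rng.standard_normal(np.shape(mu))
        return mu + np.exp(0.5 * np.asarray(logvar)) * eps

    def _source_onehot(self, source, n_rows: int) -> np.ndarray:
        """One-hot rows for a source name, an array of names, or a matrix."""
        k = len(self.sources_)
        if isinstance(source, str):
            if source not in self.sources_:
                raise ValueError(
                    f"unknown source {source!r}; registered sources: "
                    f"{list(self.sources_)}"
                )
            S = np.zeros((n_rows, k))
            S[:, list(self.sources_).index(source)] = 1.0
            return S
        source = np.asarray(source)
        if source.ndim == 1:  # array of names
            idx = np.array([self._source_index(s) for s in source])
            S = np.zeros((len(idx), k))
            S[np.arange(len(idx)), idx] = 1.0
            return S
        _validate_one_hot(source, k)
        return source.astype(float)

    def _source_index(self, name) -> int:
        try:
            return list(self.sources_).index(name)
        except ValueError:
            raise ValueError(
                f"unknown source {name!r}; registered sources: {list(self.sources_)}"
            ) from None

    def decode(self, Z, source):
        """Decode latent rows conditioned on a source (name, labels, or
        one-hot matrix). Output is non-negative (final ReLU)."""
        check_is_fitted(self, "decoder_")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        S = self._source_onehot(source, Z.shape[0])
        return self.decoder_.forward(np.concatenate([Z, S], axis=1))

    def discriminate(self, Z):
        """Adversary's softmax probabilities over sources for latent rows."""
        check_is_fitted(self, "adversary_")
        from ._nn import softmax

        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return softmax(self.adversary_.forward(Z))

    # ------------------------------------------------------------------ #
    # sklearn API

    def fit(self, X, y=None):
        """Train on a normalized matrix ``X`` with source labels ``y``.

        ``X`` may be an AnnData (source labels default to ``obs['source']``)
        or an array with ``y`` given explicitly.
        """
        from .training import fit_loop

        labels = y
        gene_ids = None
        if hasattr(X, "obs") and labels is None:
            labels = X.obs["source"].to_numpy()
        if hasattr(X, "var_names"):
            gene_ids = np.asarray(X.var_names, dtype=str)
        if labels is None:
            raise ValueError("source labels are required (pass y or AnnData obs['source'])")
        Xm = _as_matrix(X)
        labels = np.asarray(labels)
        if len(labels) != Xm.shape[0]:
            raise ValueError("label length does not match number of samples")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")

        self.sources_ = tuple(sorted(map(str, np.unique(labels))))
        rng = np.random.default_rng(self.random_state)
        self._init_networks(Xm.shape[1], len(self.sources_), rng)
        self.gene_ids_ = gene_ids
        y_idx = np.array([self._source_index(str(s)) for s in labels])
        self.history_ = fit_loop(self, Xm, y_idx, rng)
        return self

    def transform(self, X):
        """Posterior-mean embedding (n_samples, latent_dim)."""
        mu, _ = self.encode(X)
        return mu

    # ------------------------------------------------------------------ #
    # projection

    def project(self, X, target_source: str, mode: str = "mean", seed: int | None = None):
        """Decode samples as if they originated from ``target_source``.

        mode "mean" decodes the posterior mean (deterministic); "sampled"
        decodes one reparameterized draw (seeded). Returns an array, or an
        AnnData mirroring the input's obs/var when given AnnData.
        """
        if mode not in ("mean", "sampled"):
            raise ValueError("mode must be 'mean' or 'sampled'")
        if isinstance(target_source, str) and target_source not in self.sources_:
            raise ValueError(
                f"unknown target source {target_source!r}; registered sources: "
                f"{list(self.sources_)}"
            )
        if hasattr(X, "var_names") and self.gene_ids_ is not None:
            if list(map(str, X.var_names)) != list(map(str, self.gene_ids_)):
                raise ValueError("gene identifiers do not match the fitted model")
        mu, logvar = self.encode(X)
        if mode == "mean":
            z = mu
        else:
            rng = np.random.default_rng(self.random_state if seed is None else seed)
            z = self.reparameterize(mu, logvar, rng)
        out = self.decode(z, target_source)
        if hasattr(X, "obs"):
            import anndata as ad

            res = ad.AnnData(X=out, obs=X.obs.copy(), var=X.var.copy())
            res.uns["projection"] = {"target_source": target_source, "mode": mode}
            return res
        return out

    # ------------------------------------------------------------------ #
    # checkpointing

    def _all_params(self):
        return (
            self.encoder_.params
            + self.mu_head_.params
            + self.logvar_head_.params
            + self.decoder_.params
            + self.adversary_.params
        )

    def save(self, path) -> None:
        """Write a self-describing checkpoint (weights + config + sources +
        gene ids + an integrity digest) as a single .npz archive."""
        check_is_fitted(self, "encoder_")
        header = {
            "params": self.get_params(),
            "sources": list(self.sources_),
            "gene_ids": None if self.gene_ids_ is None else [str(g) for g in self.gene_ids_],
            "n_genes": int(self.n_genes_),
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self._all_params())}
        digest = _digest(header, arrays)
        np.savez(path, __header__=json.dumps(header), __digest__=digest, **arrays)

    @classmethod
    def load(cls, path) -> "BatchVAE":
        with np.load(path, allow_pickle=False) as npz:
            header = json.loads(str(npz["__header__"]))
            arrays = {k: npz[k] for k in npz.files if k.startswith("param_")}
            stored_digest = str(npz["__digest__"])
        if _digest(header, arrays) != stored_digest:
            raise ValueError("checkpoint integrity check failed (file was modified)")
        model = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in header["params"].items()})
        rng = np.random.default_rng(0)
        model.sources_ = tuple(header["sources"])
        model._init_networks(header["n_genes"], len(model.sources_), rng)
        model.gene_ids_ = (
            None if header["gene_ids"] is None else np.asarray(header["gene_ids"], dtype=str)
        )
        params = model._all_params()
        if len(params) != len(arrays):
            raise ValueError("checkpoint does not match the model architecture")
        for i, p in enumerate(params):
            stored = arrays[f"param_{i}"]
            if stored.shape != p.shape:
                raise ValueError("checkpoint does not match the model architecture")
            p[...] = stored
        model.history_ = []
        return model


def _digest(header: dict, arrays: dict) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(header, sort_keys=True).encode())
    for k in sorted(arrays):
        h.update(k.encode())
        h.update(np.ascontiguousarray(arrays[k]).tobytes())
    return h.hexdigest()
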
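"""Minibatch training for :class:`~batchvae.model.BatchVAE`.

Two realizations of the minimax objective are provided:

* ``alternating`` (default): per minibatch, (1) the adversary takes an Adam
  step minimising its NLL on the current embeddings (gradients do not reach
  the encoder), then (2) the encoder/decoder take an Adam step minimising
  ``recon + w_kl*kl - lambda_adv*adv_nll`` with the adversary frozen.
* ``gradient_reversal``: a single Adam over all parameters; the adversary's
  input gradient is reversed and scaled by ``lambda_adv`` before flowing
  into the encoder.

All randomness (shuffling, reparameterization noise) comes from the single
generator created in ``BatchVAE.fit`` from ``random_state``, so a fixed seed
reproduces the loss history bitwise on one device.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._nn import Adam, clamp_logvar, clip_global_norm, nll_from_logits
from .model import LossComponents


# training settings for the canonical 600 x 200 synthetic fixture: the
# published minibatch size (1600) exceeds the fixture, which would collapse
# every epoch into a single full-batch step; 100 preserves the minibatch
# regime at fixture scale, and three discriminator updates per VAE update
# keep the adversary near-optimal on the small problem
FIXTURE_TRAINING = {"batch_size": 100, "epochs": 300, "adversary_steps": 3}


@dataclasses.dataclass
class TrainingConfig:
    """File-friendly mirror of the BatchVAE training parameters."""

    batch_size: int = 1600
    learning_rate: float = 1e-3
    w_kl: float = 1.1e-5
    lambda_adv: float = 0.11
    epochs: int = 300
    seed: int = 0
    adversarial_mode: str = "alternating"
    stratify_batches: bool = False

    @classmethod
    def from_file(cls, path) -> "TrainingConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def estimator_params(self) -> dict:
        return {
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "w_kl": self.w_kl,
            "lambda_adv": self.lambda_adv,
            "epochs": self.epochs,
            "random_state": self.seed,
            "adversarial_mode": self.adversarial_mode,
            "stratify_batches": self.stratify_batches,
        }


class _Optimizers:
    """Adam instances bound to a model's parameter groups."""

    def __init__(self, model):
        lr = model.learning_rate
        vae_params = (
            model.encoder_.params
            + model.mu_head_.params
            + model.logvar_head_.params
            + model.decoder_.params
        )
        vae_grads = (
            model.encoder_.grads
            + model.mu_head_.grads
            + model.logvar_head_.grads
            + model.decoder_.grads
        )
        if model.adversarial_mode == "gradient_reversal":
            self.joint = Adam(
                vae_params + model.adversary_.params,
                vae_grads + model.adversary_.grads,
                lr=lr,
            )
            self.vae = self.adv = None
        else:
            self.vae = Adam(vae_params, vae_grads, lr=lr)
            self.adv = Adam(model.adversary_.params, model.adversary_.grads, lr=lr)
            self.joint = None


def _zero_vae_grads(model) -> None:
    model.encoder_.zero_grad()
    model.decoder_.zero_grad()
    for g in model.mu_head_.grads + model.logvar_head_.grads:
        g[...] = 0.0


def train_step(model, xb, yb, opts, rng) -> tuple[LossComponents, float]:
    """One minibatch update; returns the batch losses and adversary accuracy.

    ``xb`` is a (batch, genes) slice of the normalized matrix, ``yb`` the
    integer source indices. Mutates the model's weights.
    """
    if xb.shape[0] < 2:
        raise ValueError("a training batch must contain at least 2 samples")
    n = xb.shape[0]
    latent = model.latent_dim

    # shared forward: encoder -> posterior -> sample
    h = model.encoder_.forward(xb)
    mu = model.mu_head_.forward(h)
    logvar, lv_mask = clamp_logvar(model.logvar_head_.forward(h))
    eps = rng.standard_normal(mu.shape)
    z = mu + np.exp(0.5 * logvar) * eps

    k = len(model.sources_)
    S = np.zeros((n, k))
    S[np.arange(n), yb] = 1.0

    alternating = model.adversarial_mode != "gradient_reversal"

    # adversary pass on the sampled z (detached from the encoder)
    logits = model.adversary_.forward(z)
    adv_nll, dlogits, probs = nll_from_logits(logits, yb)
    adv_acc = float((probs.argmax(axis=1) == yb).mean())
    model.adversary_.zero_grad()
    dz_adv = model.adversary_.backward(dlogits)
    if alternating:
        if model.grad_clip:
            clip_global_norm(model.adversary_.grads, model.grad_clip)
        opts.adv.step()
        for _ in range(max(1, model.adversary_steps) - 1):
            logits = model.adversary_.forward(z)
            _, dlogits, _ = nll_from_logits(logits, yb)
            model.adversary_.zero_grad()
            model.adversary_.backward(dlogits)
            if model.grad_clip:
                clip_global_norm(model.adversary_.grads, model.grad_clip)
            opts.adv.step()

    # VAE pass: reconstruction through the conditional decoder
    xhat = model.decoder_.forward(np.concatenate([z, S], axis=1))
    recon = float(np.mean((xhat - xb) ** 2))
    kl = float(0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1).mean())
    loss = LossComponents(recon, kl, model.w_kl, adv_nll, model.lambda_adv)
    if not np.isfinite(loss.loss_joint):
        raise RuntimeError(
            f"non-finite loss (recon={recon}, kl={kl}, adv_nll={adv_nll}); "
            "lower the learning rate or inspect the input for NaNs"
        )

    _zero_vae_grads(model)
    dxhat = 2.0 * (xhat - xb) / xb.size
    dzcat = model.decoder_.backward(dxhat)
    dz = dzcat[:, :latent]

    if alternating:
        # re-evaluate the freshly updated adversary for the encoder's
        # adversarial gradient (adversary weights frozen in this step)
        logits2 = model.adversary_.forward(z)
        _, dlogits2, _ = nll_from_logits(logits2, yb)
        model.adversary_.zero_grad()
        dz_adv = model.adversary_.backward(dlogits2)
        model.adversary_.zero_grad()
    dz_total = dz - model.lambda_adv * dz_adv

    dmu = dz_total + model.w_kl * (mu / n)
    dlogvar = (
        dz_total * eps * 0.5 * np.exp(0.5 * logvar)
        + model.w_kl * 0.5 * (np.exp(logvar) - 1.0) / n
    ) * lv_mask

    dh = model.mu_head_.backward(dmu) + model.logvar_head_.backward(dlogvar)
    model.encoder_.backward(dh)
    if alternating:
        if model.grad_clip:
            clip_global_norm(opts.vae.grads, model.grad_clip)
        opts.vae.step()
    else:
        if model.grad_clip:
            clip_global_norm(opts.joint.grads, model.grad_clip)
        opts.joint.step()
    return loss, adv_acc


def _batch_order(y_idx, batch_size, stratify, rng) -> list[np.ndarray]:
    n = len(y_idx)
    if not stratify:
        perm = rng.permutation(n)
        return [perm[i : i + batch_size] for i in range(0, n, batch_size)]
    # proportional allocation: split each source's shuffled indices across
    # batches so every batch mirrors the global source composition
    n_batches = max(1, int(np.ceil(n / batch_size)))
    buckets: list[list[int]] = [[] for _ in range(n_batches)]
    for src in np.unique(y_idx):
        idx = rng.permutation(np.flatnonzero(y_idx == src))
        for b, chunk in enumerate(np.array_split(idx, n_batches)):
            buckets[b].extend(chunk.tolist())
    return [rng.permutation(np.array(b, dtype=int)) for b in buckets if len(b)]


def fit_loop(model, X, y_idx, rng) -> list[dict]:
    """Run the epoch loop; returns the per-epoch history."""
    opts = _Optimizers(model)
    history: list[dict] = []
    for epoch in range(model.epochs):
        batches = _batch_order(y_idx, model.batch_size, model.stratify_batches, rng)
        tot = {"recon": 0.0, "kl": 0.0, "adv_nll": 0.0, "adv_acc": 0.0}
        n_seen = 0
        for idx in batches:
            if len(idx) < 2:  # degenerate trailing batch: fold into stats only
                continue
            loss, acc = train_step(model, X[idx], y_idx[idx], opts, rng)
            w = len(idx)
            tot["recon"] += loss.recon * w
            tot["kl"] += loss.kl * w
            tot["adv_nll"] += loss.adv_nll * w
            tot["adv_acc"] += acc * w
            n_seen += w
        rec = {k: v / max(n_seen, 1) for k, v in tot.items()}
        comp = LossComponents(
            rec["recon"], rec["kl"], model.w_kl, rec["adv_nll"], model.lambda_adv
        )
        history.append(
            {
                "epoch": epoch,
                **comp.as_dict(),
                "adv_accuracy": rec["adv_acc"],
            }
        )
    return history


def write_log(history: list[dict], path) -> None:
    """Training log as line-delimited JSON, one epoch per line."""
    with open(path, "w") as fh:
        for rec in history:
            fh.write(json.dumps(rec) + "\n")


def save_checkpoint(model, path) -> None:
    """Write a self-describing model checkpoint (see BatchVAE.save)."""
    model.save(path)


def load_checkpoint(path):
    """Load a checkpoint written by :func:`save_checkpoint`."""
    from .model import BatchVAE

    return BatchVAE.load(path)


def fit(data, config: TrainingConfig | None = None, **overrides):
    """Convenience wrapper: build a BatchVAE from a TrainingConfig and fit
    on an AnnData / (X, y) pair. Returns the fitted estimator."""
    from .model import BatchVAE

    config = config or TrainingConfig()
    params = config.estimator_params()
    params.update(overrides)
    y = params.pop("y", None)
    return BatchVAE(**params).fit(data, y=y)
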
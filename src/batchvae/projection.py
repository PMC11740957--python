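"""Cross-source projection: decode samples conditioned on another origin.

Thin functional facade over :meth:`batchvae.model.BatchVAE.project` — the
mechanism that renders, e.g., a cell-line profile as if it were a clinical
tumor by swapping the decoder's one-hot source vector.
"""

from __future__ import annotations

__all__ = ["project"]


def project(model, data, target_source: str, mode: str = "mean", seed: int | None = None):
    """Decode ``data`` as if every sample originated from ``target_source``.

    mode "mean" decodes the posterior mean (deterministic); "sampled"
    decodes a seeded reparameterized draw. Sample and gene count/order are
    preserved; outputs are non-negative.
    """
    return model.project(data, target_source, mode=mode, seed=seed)
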
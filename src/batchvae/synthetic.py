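"""Synthetic multi-source RNA-seq count generator.

Emulates the structure the integration method assumes: shared biological
clusters measured under several origins ("sources") whose gene-wise
multiplicative effects and library-size scales confound the biology, plus
clusters private to a single source. Counts are negative binomial,

    count(g, i) ~ NB(mean = L_i * exp(profile_c(g)) * effect_s(g), dispersion)

with ``var = mean + dispersion * mean^2``, per-sample library scale ``L_i``
log-normal around the source's scale, cluster log-expression profile
``profile_c`` and source effect ``effect_s``. Everything is reproducible
from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = ["ClusterSpec", "SourceSpec", "SyntheticSpec", "simulate",
           "default_spec", "default_fixture", "expected_mean"]


@dataclass
class ClusterSpec:
    """A biological population: gene-wise mean log-expression and how many
    samples of it each source contributes (0 = absent, i.e. private
    elsewhere)."""

    name: str
    profile: np.ndarray  # log-scale, length n_genes
    n_per_source: dict  # source name -> sample count


@dataclass
class SourceSpec:
    """A dataset of origin: strictly positive gene-wise multiplicative
    effect (the batch effect) and a library-size scale."""

    name: str
    effect: np.ndarray
    libsize_scale: float = 300.0


@dataclass
class SyntheticSpec:
    n_genes: int
    clusters: list
    sources: list
    dispersion: float = 0.3
    libsize_sigma: float = 0.2  # log-sd of per-sample library jitter
    seed: int = 0

    def validate(self) -> None:
        if len(self.sources) < 2 or len(self.clusters) < 2:
            raise ValueError("need at least 2 sources and 2 clusters")
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("source names must be unique")
        for s in self.sources:
            if len(s.effect) != self.n_genes:
                raise ValueError(f"source {s.name}: effect length != n_genes")
            if (np.asarray(s.effect) <= 0).any():
                raise ValueError(f"source {s.name}: effects must be strictly positive")
            if s.libsize_scale <= 0:
                raise ValueError(f"source {s.name}: libsize_scale must be positive")
        for c in self.clusters:
            if len(c.profile) != self.n_genes:
                raise ValueError(f"cluster {c.name}: profile length != n_genes")
            unknown = set(c.n_per_source) - set(names)
            if unknown:
                raise ValueError(f"cluster {c.name}: unknown sources {sorted(unknown)}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def expected_mean(spec: SyntheticSpec, cluster: ClusterSpec, source: SourceSpec) -> np.ndarray:
    """Gene-wise expected count for a sample of ``cluster`` under ``source``
    at the source's nominal library scale (jitter averaged out it is scaled
    by exp(libsize_sigma^2 / 2))."""
    return source.libsize_scale * np.exp(np.asarray(cluster.profile)) * np.asarray(source.effect)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(n, p)


def simulate(spec: SyntheticSpec):
    """Generate the count matrix with per-sample truth labels.

    Returns an AnnData (samples x genes, integer counts) with
    ``obs['cluster']`` and ``obs['source']`` truth columns and
    ``obs['indication']`` set to the cluster name (a stand-in disease
    label for preprocessing filters).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    blocks, clusters, sources = [], [], []
    for c in spec.clusters:
        for s in spec.sources:
            n = int(c.n_per_source.get(s.name, 0))
            if n == 0:
                continue
            lib = s.libsize_scale * np.exp(
                rng.normal(0.0, spec.libsize_sigma, size=n)
            )
            mean = lib[:, None] * np.exp(np.asarray(c.profile))[None, :] * np.asarray(
                s.effect
            )[None, :]
            blocks.append(_nb_draw(rng, mean, spec.dispersion))
            clusters.extend([c.name] * n)
            sources.extend([s.name] * n)
    counts = np.vstack(blocks)
    n_samples = counts.shape[0]
    obs = pd.DataFrame(
        {
            "cluster": pd.Categorical(clusters),
            "source": pd.Categorical(sources),
            "indication": pd.Categorical(clusters),
        },
        index=[f"sample_{i:04d}" for i in range(n_samples)],
    )
    var = pd.DataFrame(index=[f"gene_{g:04d}" for g in range(spec.n_genes)])
    return ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)


def default_spec(seed: int = 0, n_genes: int = 200, samples_per_block: int = 60,
                 dispersion: float = 0.3, effect_sigma: float = 0.5,
                 n_markers: int = 20, marker_shift: float = 2.0) -> SyntheticSpec:
    """The canonical study conditions: 3 sources x 4 clusters, 200 genes,
    600 samples, with the fourth cluster private to the first source.

    Each cluster up-regulates its own block of ``n_markers`` genes by
    ``marker_shift`` (natural-log units) over a shared baseline profile;
    each source applies gene-wise log-normal(0, effect_sigma^2)
    multiplicative distortions — a batch effect strong enough that raw
    log-CPM profiles separate by source.
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, 1.0, size=n_genes)
    source_names = ["cell_line", "xenograft", "tumor"]
    sources = [
        SourceSpec(
            name=name,
            effect=np.exp(rng.normal(0.0, effect_sigma, size=n_genes)),
            libsize_scale=300.0,
        )
        for name in source_names
    ]
    clusters = []
    for ci in range(4):
        profile = baseline.copy()
        lo = ci * n_markers
        profile[lo : lo + n_markers] += marker_shift
        if ci < 3:
            n_per = {name: samples_per_block for name in source_names}
        else:  # private population: present in the first source only
            n_per = {source_names[0]: samples_per_block}
        clusters.append(ClusterSpec(f"cluster_{ci}", profile, n_per))
    return SyntheticSpec(
        n_genes=n_genes,
        clusters=clusters,
        sources=sources,
        dispersion=dispersion,
        seed=seed,
    )


def default_fixture(seed: int = 0):
    """Simulate the canonical 600-sample, 200-gene fixture (see
    :func:`default_spec`)."""
    return simulate(default_spec(seed=seed))
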
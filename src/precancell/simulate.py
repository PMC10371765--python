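"""Synthetic labeled scRNA-seq datasets with planted marker structure.

The generator emulates the statistical features that marker discovery and
k-NN classification actually exercise: overdispersed UMI counts
(gamma-mixed Poisson, i.e. negative binomial), per-cell library-size
variation, independent dropout-style zero inflation, and a minority of
genes with a class-specific log-mean shift — planted up-in-malignant
("TMG-like") and up-in-non-malignant ("NMG-like") genes. Counts are passed
through UMI depth normalization so downstream modules see log-normalized
matrices. No attempt is made to copy any real dataset's empirical
distribution (no batch effects, cell cycle, doublets, or subtypes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .markers import MALIGNANT, NON_MALIGNANT, ReferenceDataset
from .matrix import ExpressionMatrix, Normalization, normalize_umi


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic labeled dataset.

    ``effect_size`` is the natural-log shift applied to the mean of planted
    marker genes in their favored class; ``dispersion`` is the negative
    binomial inverse-size parameter (variance = mu + dispersion * mu^2);
    ``dropout_rate`` is the probability that any count is zeroed
    independently of its magnitude; ``library_size_mean`` is the expected
    total UMI count per cell.
    """

    n_malignant: int = 300
    n_non_malignant: int = 300
    n_genes: int = 2000
    n_tmg_planted: int = 25
    n_nmg_planted: int = 50
    effect_size: float = 2.0
    dropout_rate: float = 0.2
    dispersion: float = 0.5
    library_size_mean: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_malignant, self.n_non_malignant, self.n_genes) < 1:
            raise ValueError("cell and gene counts must be positive")
        if self.n_tmg_planted < 0 or self.n_nmg_planted < 0:
            raise ValueError("planted marker counts must be non-negative")
        if self.n_tmg_planted + self.n_nmg_planted > self.n_genes:
            raise ValueError("cannot plant more markers than genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion and library_size_mean must be positive")


@dataclass
class SyntheticDataset:
    """A generated :class:`ReferenceDataset` plus the planted ground truth."""

    dataset: ReferenceDataset
    planted_tmg: list[str]
    planted_nmg: list[str]

    def __post_init__(self) -> None:
        if set(self.planted_tmg) & set(self.planted_nmg):
            raise ValueError("planted marker lists must be disjoint")


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def _default_planted(cfg: SimulationConfig) -> tuple[list[int], list[int]]:
    tmg_idx = list(range(cfg.n_tmg_planted))
    nmg_idx = list(range(cfg.n_tmg_planted, cfg.n_tmg_planted + cfg.n_nmg_planted))
    return tmg_idx, nmg_idx


def _simulate(
    cfg: SimulationConfig,
    tmg_idx: list[int],
    nmg_idx: list[int],
    seed: int,
    name: str,
) -> SyntheticDataset:
    rng = np.random.default_rng(seed)
    n_cells = cfg.n_malignant + cfg.n_non_malignant
    genes = _gene_ids(cfg.n_genes)

    # relative expression: nulls span several orders of magnitude; planted
    # markers sit in the detectably expressed regime (as real marker genes
    # do), so the detection-fraction filter is exercised rather than
    # trivially failed
    weight = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    planted = np.array(tmg_idx + nmg_idx, dtype=int)
    if planted.size:
        weight[planted] = rng.lognormal(mean=np.log(2.0), sigma=0.5, size=planted.size)

    library = rng.lognormal(mean=np.log(cfg.library_size_mean), sigma=0.3, size=n_cells)
    mu = np.outer(weight / weight.sum(), library)

    malignant = np.zeros(n_cells, dtype=bool)
    malignant[: cfg.n_malignant] = True
    boost = np.exp(cfg.effect_size)
    if tmg_idx:
        mu[np.ix_(tmg_idx, np.flatnonzero(malignant))] *= boost
    if nmg_idx:
        mu[np.ix_(nmg_idx, np.flatnonzero(~malignant))] *= boost

    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape=shape, scale=mu * cfg.dispersion)
    counts = rng.poisson(lam).astype(float)
    if cfg.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= cfg.dropout_rate

    cell_ids = [
        f"{'mal' if malignant[j] else 'non'}_{j:05d}" for j in range(n_cells)
    ]
    raw = ExpressionMatrix(counts, genes, cell_ids, Normalization.RAW)
    labels = np.where(malignant, MALIGNANT, NON_MALIGNANT)
    dataset = ReferenceDataset(expr=normalize_umi(raw), labels=labels, name=name)
    return SyntheticDataset(
        dataset=dataset,
        planted_tmg=[genes[i] for i in tmg_idx],
        planted_nmg=[genes[i] for i in nmg_idx],
    )


def simulate_dataset(cfg: SimulationConfig, name: str = "synthetic") -> SyntheticDataset:
    """Generate one labeled dataset; deterministic for a given config.

    Planted up-in-malignant genes occupy the first ``n_tmg_planted`` gene
    slots and planted up-in-non-malignant genes the next ``n_nmg_planted``,
    so repeated draws from the same config (e.g. a reference panel and a
    fresh query) share their planted marker identities.
    """
    tmg_idx, nmg_idx = _default_planted(cfg)
    return _simulate(cfg, tmg_idx, nmg_idx, cfg.seed, name)


def simulate_reference_panel(
    cfg: SimulationConfig,
    n_references: int = 5,
    shared_marker_fraction: float = 1.0,
) -> list[SyntheticDataset]:
    """Generate a panel of reference datasets with partially shared markers.

    A ``shared_marker_fraction`` of the planted markers (rounded down) is
    common to every panel member; the remainder are panel-private genes,
    drawn from disjoint gene blocks so that a private marker of one panel
    is a null gene in every other. Panel member ``i`` uses derived seed
    ``cfg.seed + 1 + i``.
    """
    if n_references < 1:
        raise ValueError("n_references must be >= 1")
    if not 0 <= shared_marker_fraction <= 1:
        raise ValueError("shared_marker_fraction must be in [0, 1]")
    tmg_idx, nmg_idx = _default_planted(cfg)
    n_shared_t = int(round(shared_marker_fraction * len(tmg_idx)))
    n_shared_n = int(round(shared_marker_fraction * len(nmg_idx)))
    n_priv_t = len(tmg_idx) - n_shared_t
    n_priv_n = len(nmg_idx) - n_shared_n
    per_panel_private = n_priv_t + n_priv_n
    base = len(tmg_idx) + len(nmg_idx)
    if base + n_references * per_panel_private > cfg.n_genes:
        raise ValueError("not enough genes for panel-private markers")

    panels = []
    for i in range(n_references):
        start = base + i * per_panel_private
        panel_tmg = tmg_idx[:n_shared_t] + list(range(start, start + n_priv_t))
        panel_nmg = nmg_idx[:n_shared_n] + list(
            range(start + n_priv_t, start + per_panel_private)
        )
        panels.append(_simulate(cfg, panel_tmg, panel_nmg, cfg.seed + 1 + i, f"ref_{i}"))
    return panels


def fresh_query(cfg: SimulationConfig, offset: int = 1000) -> SyntheticDataset:
    """An independent draw from the same generative process (same planted
    marker identities), for train/test experiments."""
    return simulate_dataset(dataclasses.replace(cfg, seed=cfg.seed + offset), name="query")
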
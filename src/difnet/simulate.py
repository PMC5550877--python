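"""Synthetic paired-condition expression data with planted structure.

The generator emits a control matrix and one or more perturbed matrices that
share a deterministic planted layout: latent-factor co-expression modules,
designated hub genes whose attachments to partner genes are partly removed
("rewired") in the perturbed condition, and a subset of genes shifted by a
fixed log2 fold change.  A :class:`PlantedTruth` manifest records the ground
truth so downstream degree-difference statistics can be scored against it.

Model (log2 scale, then exponentiated to linear scale):

* every gene g has a baseline mean ``mu_g ~ N(6, 1)``;
* module members load on one latent factor per module so that pairwise
  within-module Pearson correlation equals ``within_module_corr``;
* each hub's partners are split into a "kept" and a "removed" group, each
  sharing its own latent factor; the hub loads on both group factors in the
  control condition and only on the kept-group factor in the perturbed
  condition (the removed-group loading is replaced by fresh noise of equal
  variance, so the hub's marginal variance is unchanged);
* the number of kept partners is ``ceil((1 - rewire_fraction) * hub_degree)``;
* differentially expressed genes receive ``+/- de_log2fc`` on their
  perturbed-condition mean (alternating signs, hubs and partners first so
  that planted network structure survives DE-based gene selection);
* the residual standard deviation on the log2 scale is ``noise_sd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "kept_partner_count",
    "generate_expression",
    "generate_paired",
    "generate_annotations",
]

# sub-stream indices hung off the single global seed
_STREAM_STRUCTURE = 0
_STREAM_CONTROL = 1
_STREAM_PERTURBED = 2  # + perturbation index
_STREAM_ANNOTATIONS = 17

# share of hub variance given to private noise (rest split across group factors)
_HUB_NOISE_VAR = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure generator."""

    n_genes: int = 200
    n_samples_per_condition: int = 30
    n_modules: int = 2
    module_size: int = 10
    n_hub_genes: int = 2
    hub_degree: int = 10
    rewire_fraction: float = 0.8
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    within_module_corr: float = 0.8
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first violated bound."""
        c = self
        if c.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {c.n_genes}")
        if c.n_samples_per_condition < 1:
            raise ConfigurationError(
                f"n_samples_per_condition must be >= 1, got {c.n_samples_per_condition}"
            )
        if c.n_modules < 0 or c.module_size < 0 or c.n_hub_genes < 0 or c.hub_degree < 0:
            raise ConfigurationError("counts must be nonnegative")
        if c.n_modules * c.module_size > c.n_genes:
            raise ConfigurationError(
                f"n_modules * module_size ({c.n_modules * c.module_size}) "
                f"exceeds n_genes ({c.n_genes})"
            )
        if c.n_hub_genes > c.n_modules:
            raise ConfigurationError(
                f"n_hub_genes ({c.n_hub_genes}) exceeds n_modules ({c.n_modules})"
            )
        if c.hub_degree >= c.n_genes:
            raise ConfigurationError(
                f"hub_degree ({c.hub_degree}) must be smaller than n_genes ({c.n_genes})"
            )
        needed = c.n_modules * c.module_size + c.n_hub_genes * (1 + c.hub_degree)
        if needed > c.n_genes:
            raise ConfigurationError(
                f"layout needs {needed} genes (modules + hubs + partners) "
                f"but n_genes is {c.n_genes}"
            )
        if not 0.0 <= c.rewire_fraction <= 1.0:
            raise ConfigurationError(
                f"rewire_fraction must be in [0, 1], got {c.rewire_fraction}"
            )
        if not 0.0 <= c.de_fraction <= 1.0:
            raise ConfigurationError(f"de_fraction must be in [0, 1], got {c.de_fraction}")
        if not 0.0 < c.within_module_corr < 1.0:
            raise ConfigurationError(
                f"within_module_corr must be in (0, 1), got {c.within_module_corr}"
            )
        if not c.noise_sd > 0:
            raise ConfigurationError(f"noise_sd must be positive, got {c.noise_sd}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of one simulation.

    ``planted_edges_by_condition`` records the hub-to-partner attachments per
    condition as sets of lexicographically ordered gene pairs; module
    co-membership is recorded separately in ``module_membership``.
    """

    gene_ids: tuple[str, ...]
    de_genes: Mapping[str, int]  # gene -> +1 / -1 (sign of planted change)
    module_membership: Mapping[str, str]
    hub_genes: tuple[str, ...]
    planted_edges_by_condition: Mapping[str, frozenset[tuple[str, str]]]
    expected_dif_degree: Mapping[str, int]

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        if not set(self.hub_genes) <= genes:
            raise ConfigurationError("hub_genes must be a subset of gene_ids")
        for label, edges in self.planted_edges_by_condition.items():
            for a, b in edges:
                if a == b:
                    raise ConfigurationError(f"self-pair {a!r} in condition {label!r}")

    def partners_of(self, hub: str, condition: str = "control") -> list[str]:
        edges = self.planted_edges_by_condition[condition]
        out = [b if a == hub else a for a, b in edges if hub in (a, b)]
        return sorted(out)


def kept_partner_count(hub_degree: int, rewire_fraction: float) -> int:
    """Number of hub edges retained in the perturbed condition.

    ``ceil((1 - rewire_fraction) * hub_degree)``, with the product rounded to
    nine decimals first so binary float artifacts cannot shift the ceiling.
    """
    return int(math.ceil(round((1.0 - rewire_fraction) * hub_degree, 9)))


@dataclass(frozen=True)
class _Layout:
    gene_ids: tuple[str, ...]
    modules: Mapping[str, tuple[int, ...]]  # module id -> gene indices
    hubs: tuple[int, ...]
    partners: Mapping[int, tuple[int, ...]]  # hub index -> partner indices
    kept: Mapping[int, tuple[int, ...]]
    removed: Mapping[int, tuple[int, ...]]
    de_idx: tuple[int, ...]
    de_sign: tuple[int, ...]
    mu: np.ndarray


def _build_layout(cfg: SimulationConfig) -> _Layout:
    rng = np.random.default_rng([cfg.seed, _STREAM_STRUCTURE])
    width = max(4, len(str(cfg.n_genes)))
    gene_ids = tuple(f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1))

    cursor = 0
    modules: dict[str, tuple[int, ...]] = {}
    for m in range(cfg.n_modules):
        modules[f"M{m + 1}"] = tuple(range(cursor, cursor + cfg.module_size))
        cursor += cfg.module_size
    hubs = tuple(range(cursor, cursor + cfg.n_hub_genes))
    cursor += cfg.n_hub_genes
    partners: dict[int, tuple[int, ...]] = {}
    for h in hubs:
        partners[h] = tuple(range(cursor, cursor + cfg.hub_degree))
        cursor += cfg.hub_degree
    k = kept_partner_count(cfg.hub_degree, cfg.rewire_fraction)
    kept = {h: p[:k] for h, p in partners.items()}
    removed = {h: p[k:] for h, p in partners.items()}

    mu = rng.normal(6.0, 1.0, cfg.n_genes)

    # DE pool: hubs and partners first (so planted network structure is
    # recoverable through DE-based gene selection), then a shuffled remainder.
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    structured = list(hubs) + [p for h in hubs for p in partners[h]]
    remainder = [i for i in range(cfg.n_genes) if i not in set(structured)]
    pool = structured + list(rng.permutation(remainder))
    de_idx = tuple(pool[:n_de])
    de_sign = tuple(1 if j % 2 == 0 else -1 for j in range(n_de))
    return _Layout(
        gene_ids=gene_ids,
        modules=modules,
        hubs=hubs,
        partners=partners,
        kept=kept,
        removed=removed,
        de_idx=de_idx,
        de_sign=de_sign,
        mu=mu,
    )


def _factor_rows(rng: np.random.Generator, k: int, n_s: int) -> np.ndarray:
    """Draw k latent factors of length n_s, orthogonalized in-sample.

    When ``k <= n_s - 1`` the raw Gaussian draws are centered and
    QR-orthonormalized, then rescaled to exact zero mean and unit sample
    variance; realized pairwise factor correlations are then exactly zero,
    so planted structure is not blurred by incidental factor overlap at
    small sample sizes.  With too few samples the raw draws are returned.
    """
    raw = rng.standard_normal((n_s, k))
    if k == 0 or k > n_s - 1:
        return raw.T
    centered = raw - raw.mean(axis=0)
    q, r = np.linalg.qr(centered)
    q = q * np.where(np.diag(r) < 0, -1.0, 1.0)  # sign-fix for determinism
    return (q * math.sqrt(n_s)).T


def _draw_condition(
    cfg: SimulationConfig,
    layout: _Layout,
    rng: np.random.Generator,
    label: str,
    perturbed: bool,
) -> ExpressionMatrix:
    n_g, n_s = cfg.n_genes, cfg.n_samples_per_condition
    rho = cfg.within_module_corr
    sd_tot = cfg.noise_sd / math.sqrt(1.0 - rho)

    # fixed draw order keeps the stream reproducible
    resid = rng.standard_normal((n_g, n_s))
    x = cfg.noise_sd * resid  # background genes

    # factor layout: one per module, then (kept, removed, fresh) per hub
    factors = _factor_rows(rng, cfg.n_modules + 3 * cfg.n_hub_genes, n_s)

    for m, members in enumerate(layout.modules.values()):
        f = factors[m]
        idx = np.asarray(members, dtype=int)
        x[idx] = sd_tot * (
            math.sqrt(rho) * f[None, :] + math.sqrt(1.0 - rho) * resid[idx]
        )

    for j, h in enumerate(layout.hubs):
        base = cfg.n_modules + 3 * j
        g_kept, g_removed, eta = factors[base], factors[base + 1], factors[base + 2]
        d = cfg.hub_degree
        if d == 0:
            continue
        for group, factor in ((layout.kept[h], g_kept), (layout.removed[h], g_removed)):
            if group:
                idx = np.asarray(group, dtype=int)
                x[idx] = sd_tot * (
                    math.sqrt(rho) * factor[None, :]
                    + math.sqrt(1.0 - rho) * resid[idx]
                )
        lam_k = math.sqrt((1.0 - _HUB_NOISE_VAR) * len(layout.kept[h]) / d)
        lam_r = math.sqrt((1.0 - _HUB_NOISE_VAR) * len(layout.removed[h]) / d)
        removed_factor = eta if perturbed else g_removed
        x[h] = sd_tot * (
            lam_k * g_kept
            + lam_r * removed_factor
            + math.sqrt(_HUB_NOISE_VAR) * resid[h]
        )

    x += layout.mu[:, None]
    if perturbed and layout.de_idx:
        idx = np.asarray(layout.de_idx, dtype=int)
        x[idx] += np.asarray(layout.de_sign, dtype=float)[:, None] * cfg.de_log2fc

    values = pd.DataFrame(
        np.exp2(x),
        index=list(layout.gene_ids),
        columns=[f"{label}_s{j:03d}" for j in range(1, n_s + 1)],
    )
    conditions = {s: label for s in values.columns}
    return ExpressionMatrix(values=values, conditions=conditions)


def _truth_from_layout(
    cfg: SimulationConfig, layout: _Layout, perturbation_labels: Sequence[str]
) -> PlantedTruth:
    ids = layout.gene_ids

    def pair(i: int, j: int) -> tuple[str, str]:
        a, b = sorted((ids[i], ids[j]))
        return (a, b)

    control_edges = frozenset(
        pair(h, p) for h in layout.hubs for p in layout.partners[h]
    )
    kept_edges = frozenset(pair(h, p) for h in layout.hubs for p in layout.kept[h])
    edges = {"control": control_edges}
    for label in perturbation_labels:
        edges[label] = kept_edges
    k = kept_partner_count(cfg.hub_degree, cfg.rewire_fraction)
    expected = {ids[h]: cfg.hub_degree - k for h in layout.hubs}
    membership = {
        ids[i]: mid for mid, members in layout.modules.items() for i in members
    }
    de = {ids[i]: s for i, s in zip(layout.de_idx, layout.de_sign)}
    return PlantedTruth(
        gene_ids=ids,
        de_genes=de,
        module_membership=membership,
        hub_genes=tuple(ids[h] for h in layout.hubs),
        planted_edges_by_condition=edges,
        expected_dif_degree=expected,
    )


def generate_paired(
    config: SimulationConfig,
    perturbation_labels: Sequence[str] = ("perturbed",),
    control_label: str = "control",
) -> tuple[ExpressionMatrix, dict[str, ExpressionMatrix], PlantedTruth]:
    """Generate a control matrix plus one matrix per perturbation label.

    All perturbations share the planted layout (same hubs, same removed
    edges, same DE genes) but draw independent samples, mimicking replicate
    perturbation lines profiled against a common control.
    """
    config.validate()
    labels = list(perturbation_labels)
    if not labels:
        raise ConfigurationError("at least one perturbation label is required")
    if control_label in labels or len(set(labels)) != len(labels):
        raise ConfigurationError("condition labels must be distinct")
    layout = _build_layout(config)
    control = _draw_condition(
        config,
        layout,
        np.random.default_rng([config.seed, _STREAM_CONTROL]),
        control_label,
        perturbed=False,
    )
    perturbed = {}
    for i, label in enumerate(labels):
        rng = np.random.default_rng([config.seed, _STREAM_PERTURBED + i])
        perturbed[label] = _draw_condition(config, layout, rng, label, perturbed=True)
    truth = _truth_from_layout(config, layout, labels)
    # rename the control edge key if a custom control label was used
    if control_label != "control":
        edges = dict(truth.planted_edges_by_condition)
        edges[control_label] = edges.pop("control")
        truth = replace(truth, planted_edges_by_condition=edges)
    return control, perturbed, truth


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Single-perturbation convenience wrapper around :func:`generate_paired`."""
    control, perturbed, truth = generate_paired(config, ("perturbed",))
    return control, perturbed["perturbed"], truth


def generate_annotations(
    truth: PlantedTruth,
    n_terms: int,
    term_size_range: tuple[int, int],
    n_enriched_terms: int,
    seed: int,
):
    """Build a GMT-style annotation map over the simulated gene universe.

    The first ``n_enriched_terms`` terms are seeded with planted structure
    (a hub, its partners, one module) and padded with planted DE genes, so
    Fisher enrichment against the planted DE set should flag them; the
    remaining terms are uniform random draws from the universe.
    """
    from .enrich import AnnotationMap  # local import avoids a cycle

    if n_terms < 0 or n_enriched_terms < 0:
        raise ConfigurationError("term counts must be nonnegative")
    if n_enriched_terms > n_terms:
        raise ConfigurationError(
            f"n_enriched_terms ({n_enriched_terms}) exceeds n_terms ({n_terms})"
        )
    lo, hi = term_size_range
    universe = list(truth.gene_ids)
    if not 1 <= lo <= hi:
        raise ConfigurationError(f"invalid term_size_range ({lo}, {hi})")
    if hi > len(universe):
        raise ConfigurationError(
            f"term size bound {hi} exceeds the gene universe ({len(universe)})"
        )
    rng = np.random.default_rng([seed, _STREAM_ANNOTATIONS])
    hubs = sorted(truth.hub_genes)
    modules = sorted(set(truth.module_membership.values()))
    members_by_module = {
        m: sorted(g for g, mm in truth.module_membership.items() if mm == m)
        for m in modules
    }
    de_sorted = sorted(truth.de_genes)
    control_label = (
        "control" if "control" in truth.planted_edges_by_condition else None
    )

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    width = max(4, len(str(n_terms)))
    for i in range(n_terms):
        tid = f"T{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched_terms:
            core: set[str] = set()
            if hubs:
                hub = hubs[i % len(hubs)]
                core.add(hub)
                if control_label:
                    core.update(truth.partners_of(hub, control_label))
            if modules:
                core.update(members_by_module[modules[i % len(modules)]])
            pad = [g for g in de_sorted if g not in core]
            if len(core) < size and pad:
                take = min(size - len(core), len(pad))
                core.update(map(str, rng.choice(pad, size=take, replace=False)))
            rest = [g for g in universe if g not in core]
            if len(core) < size and rest:
                take = min(size - len(core), len(rest))
                core.update(map(str, rng.choice(rest, size=take, replace=False)))
            genes = frozenset(core)
            name = "planted_enriched"
        else:
            genes = frozenset(map(str, rng.choice(universe, size=size, replace=False)))
            name = "random"
        terms[tid] = (name, genes)
    return AnnotationMap(terms=terms, universe=frozenset(universe))
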
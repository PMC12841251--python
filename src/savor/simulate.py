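"""Synthetic inputs for every pipeline stage.

The study design being emulated: 4 live-preservation groups x 6 crabs, with
flavor compounds reported as mean +/- SD (mg/100 g); RNA-seq contrasts
summarised as per-gene log2 fold changes with FDR; and genes x samples
expression matrices carrying co-expressed modules. Three generators cover
these:

* :func:`gen_panel` — per-animal compound concentrations drawn from
  truncated normals around a mean/SD grid (default: the packaged panel
  summary, i.e. the published group means and SDs at n = 6).
* :func:`gen_expression` — latent-factor expression matrices with planted
  modules and group fold-change effects, returning the planted truth.
* :func:`gen_deg_table` — a DEG table with a known planted set, for
  filter-recovery tests.

All generators are bit-reproducible for a given (spec, seed); the panel
generator derives an independent substream per (compound, group) so adding
a compound never shifts any other compound's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .taste import load_panel_summary

__all__ = ["PanelSpec", "ExprSimSpec", "gen_panel", "gen_expression", "gen_deg_table"]


@dataclass
class PanelSpec:
    """Mean/SD grid plus design constants for a compound panel simulation.

    ``summary`` is long-format ``compound, group, mean, sd`` in mg/100 g.
    Draws are truncated at zero by resampling, matching the physical
    constraint that concentrations are non-negative.
    """

    summary: pd.DataFrame
    n_replicates: int = 6
    seed: int = 0
    distribution: str = "truncnorm"  # or "lognormal"

    @classmethod
    def default(cls, seed: int = 0, n_replicates: int = 6) -> "PanelSpec":
        """The packaged study grid: 23 compounds x 3 groups, n = 6."""
        return cls(summary=load_panel_summary(), n_replicates=n_replicates, seed=seed)

    def validate(self) -> None:
        required = {"compound", "group", "mean", "sd"}
        missing = required - set(self.summary.columns)
        if missing:
            raise ValueError(f"panel summary missing columns: {sorted(missing)}")
        if (self.summary["sd"] < 0).any():
            raise ValueError("sd must be non-negative")
        if (self.summary["mean"] < 0).any():
            raise ValueError("means must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.distribution not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown distribution: {self.distribution}")


def _substream(seed: int, *key: str) -> np.random.Generator:
    """Independent generator keyed by (seed, names): stable across panel edits."""
    digest = hashlib.sha256("\x1f".join(key).encode()).digest()
    entropy = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, entropy]))


def gen_panel(spec: PanelSpec) -> pd.DataFrame:
    """Simulate per-animal concentrations for every (compound, group).

    Truncated-normal draws (negative values resampled); with ``sd = 0``
    every replicate equals the mean. Returns a long table ``compound,
    group, replicate, concentration``.
    """
    spec.validate()
    rows = []
    for row in spec.summary.itertuples():
        rng = _substream(spec.seed, "panel", str(row.compound), str(row.group))
        if spec.distribution == "lognormal" and row.mean > 0 and row.sd > 0:
            # moment-matched lognormal alternative
            var = row.sd**2
            mu = np.log(row.mean**2 / np.sqrt(var + row.mean**2))
            sigma = np.sqrt(np.log(1.0 + var / row.mean**2))
            draws = rng.lognormal(mu, sigma, size=spec.n_replicates)
        else:
            draws = rng.normal(row.mean, row.sd, size=spec.n_replicates)
            for _ in range(1000):
                neg = draws < 0
                if not neg.any():
                    break
                draws[neg] = rng.normal(row.mean, row.sd, size=int(neg.sum()))
            draws = np.maximum(draws, 0.0)
        for rep, value in enumerate(draws, start=1):
            rows.append(
                {
                    "compound": row.compound,
                    "group": row.group,
                    "replicate": rep,
                    "concentration": float(value),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExprSimSpec:
    """Design of a planted-module expression simulation.

    Genes in module m follow ``x_gs = loading * f_ms + noise_sd * eps`` with
    a shared latent factor f per module and sample; leftover genes are pure
    noise. ``log2fc`` (per planted-module effect) is added to the second
    group's samples, so the matrix is interpreted as log2-scale expression.
    """

    n_genes: int = 300
    n_samples_per_group: int = 6
    groups: Sequence[str] = ("ICE48", "LTA48")
    module_sizes: Sequence[int] = (40, 40, 40, 40, 40)
    loading: float = 0.9
    noise_sd: float = 0.3
    module_log2fc: Sequence[float] = field(default_factory=tuple)
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the number of genes")
        if not 0 < self.loading <= 1:
            raise ValueError("loading must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.module_log2fc and len(self.module_log2fc) != len(self.module_sizes):
            raise ValueError("module_log2fc must match module_sizes")


def gen_expression(spec: ExprSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a genes x samples matrix with planted co-expression modules.

    Returns ``(matrix, truth)`` where truth holds ``module`` (gene -> module
    id, -1 for background), ``true_log2fc`` (gene -> planted group effect)
    and ``sample_group``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    n_groups = len(spec.groups)
    n_samples = n_groups * spec.n_samples_per_group
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    samples = [
        f"{g}_r{r + 1}" for g in spec.groups for r in range(spec.n_samples_per_group)
    ]
    sample_group = np.repeat(np.arange(n_groups), spec.n_samples_per_group)

    module_of = np.full(spec.n_genes, -1, dtype=int)
    start = 0
    for mid, size in enumerate(spec.module_sizes):
        module_of[start : start + size] = mid
        start += size

    factors = rng.standard_normal((len(spec.module_sizes), n_samples))
    x = spec.noise_sd * rng.standard_normal((spec.n_genes, n_samples))
    for gi in range(spec.n_genes):
        if module_of[gi] >= 0:
            x[gi] += spec.loading * factors[module_of[gi]]

    fc = np.zeros(spec.n_genes)
    if spec.module_log2fc:
        for mid, effect in enumerate(spec.module_log2fc):
            fc[module_of == mid] = effect
        # planted effect enters group 2..k samples on the log2 scale
        x[:, sample_group > 0] += fc[:, None]

    matrix = pd.DataFrame(x, index=genes, columns=samples)
    truth = {
        "module": dict(zip(genes, module_of.tolist())),
        "true_log2fc": dict(zip(genes, fc.tolist())),
        "sample_group": dict(zip(samples, (spec.groups[g] for g in sample_group))),
    }
    return matrix, truth


def gen_deg_table(
    n_genes: int = 1000,
    n_de: int = 100,
    lfc_effect: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, set]:
    """DEG table with ``n_de`` planted genes at |log2fc| >= 1 and tiny FDR.

    Null genes get log2fc ~ N(0, 0.25) clipped inside (-1, 1) and uniform
    p-values; planted genes get +/- ``lfc_effect`` and p-values small enough
    to survive BH at 5%. Returns the table (with BH FDR filled in) and the
    planted gene-id set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**21]))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    planted = set(rng.choice(genes, size=n_de, replace=False).tolist())
    lfc = np.clip(rng.normal(0, 0.25, n_genes), -0.99, 0.99)
    pvals = rng.uniform(0.0, 1.0, n_genes)
    for i, g in enumerate(genes):
        if g in planted:
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            lfc[i] = sign * (lfc_effect + rng.exponential(0.5))
            pvals[i] = rng.uniform(0, 1e-8)
    from .stats import benjamini_hochberg

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": benjamini_hochberg(pvals),
        }
    )
    return table, planted
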
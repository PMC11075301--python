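"""Synthetic longitudinal community generator.

Counts follow a compositional log-normal model: per-sample latent
log-abundances are multivariate normal with block-diagonal exchangeable
correlation (``rho_within`` inside planted blocks, zero elsewhere), and
reads are multinomial draws at fixed depth from the softmax of the
latents. A configurable treatment effect hits one group at month 1 -
depleting a fraction of taxa, boosting the most abundant taxa, and
weakening within-block correlation - and decays exponentially,
halving every ``recovery_halflife`` months.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .table_io import FeatureTable

BACKGROUND_BLOCK = 0


@dataclass
class SyntheticConfig:
    n_asv: int = 300
    n_blocks: int = 10
    block_size: int = 10
    rho_within: float = 0.9
    groups: tuple = ("A", "C")
    treated_group: str = "A"
    months: tuple = tuple(range(1, 15))
    samples_per_group_month: int = 8
    depth: int = 20_000
    effect_richness: float = 0.3
    effect_dominance: float = 2.0
    effect_network: float = 0.3
    recovery_halflife: float = 3.0
    seed: int = 0
    # model shape knobs (not part of the experimental design)
    base_log_sd: float = 2.0
    latent_sd: float = 1.5
    depletion_log_units: float = 6.0
    dominance_top_fraction: float = 0.05

    def validate(self) -> None:
        if self.n_blocks * self.block_size > self.n_asv:
            raise ConfigurationError("planted blocks exceed n_asv")
        if not 0 <= self.rho_within < 1:
            raise ConfigurationError("rho_within must lie in [0, 1)")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if self.recovery_halflife <= 0:
            raise ConfigurationError("recovery_halflife must be positive")
        if not 0 <= self.effect_richness <= 1:
            raise ConfigurationError("effect_richness must lie in [0, 1]")
        if not 0 <= self.effect_network <= 1:
            raise ConfigurationError("effect_network must lie in [0, 1]")
        if self.treated_group not in self.groups:
            raise ConfigurationError("treated_group must be one of groups")
        if self.samples_per_group_month <= 0 or not self.months:
            raise ConfigurationError("need at least one sample and one month")


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    block_membership: dict  # asv id -> block id (0 = background)
    effect_trajectory: dict  # month -> decay factor in (0, 1]
    depleted_asvs: list
    boosted_asvs: list
    latents: pd.DataFrame | None = None  # asv x sample latent log-abundance

    def to_json(self, path) -> None:
        payload = {
            "block_membership": self.block_membership,
            "effect_trajectory": {str(k): v for k, v in self.effect_trajectory.items()},
            "depleted_asvs": self.depleted_asvs,
            "boosted_asvs": self.boosted_asvs,
        }
        if self.latents is not None:
            payload["latents"] = {
                "asv_ids": list(self.latents.index),
                "sample_ids": list(self.latents.columns),
                "values": np.round(self.latents.to_numpy(), 6).tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _decay(month: int, first_month: int, halflife: float) -> float:
    return 2.0 ** (-(month - first_month) / halflife)


def generate_counts(config: SyntheticConfig) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate the full two-group longitudinal count table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_asv
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n)]
    block_of = np.zeros(n, dtype=int)
    for b in range(config.n_blocks):
        lo = b * config.block_size
        block_of[lo:lo + config.block_size] = b + 1

    base_mu = rng.normal(0.0, config.base_log_sd, size=n)
    n_depleted = round(config.effect_richness * n)
    depleted = rng.choice(n, size=n_depleted, replace=False) if n_depleted else np.array([], dtype=int)
    depleted_mask = np.zeros(n, dtype=bool)
    depleted_mask[depleted] = True
    n_top = max(1, math.ceil(config.dominance_top_fraction * n))
    boosted = np.argsort(base_mu)[::-1][:n_top]
    boosted_mask = np.zeros(n, dtype=bool)
    boosted_mask[boosted] = True
    first_month = min(config.months)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    latent_cols: list[np.ndarray] = []
    count_cols: list[np.ndarray] = []
    trajectory: dict[int, float] = {}
    for month in config.months:
        f = _decay(month, first_month, config.recovery_halflife)
        trajectory[int(month)] = f
        for group in config.groups:
            treated = group == config.treated_group
            rho = config.rho_within
            if treated:
                rho = rho * (1.0 - (1.0 - config.effect_network) * f)
            sq_shared = math.sqrt(rho)
            sq_noise = math.sqrt(1.0 - rho)
            for rep in range(config.samples_per_group_month):
                sid = f"{group}{rep + 1:02d}M{month:02d}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "group": group, "month": int(month),
                     "subject": f"{group}{rep + 1:02d}"}
                )
                shared = rng.normal(0.0, 1.0, size=config.n_blocks)
                eps = rng.normal(0.0, 1.0, size=n)
                z = eps.copy()
                in_block = block_of > 0
                z[in_block] = (
                    sq_shared * shared[block_of[in_block] - 1]
                    + sq_noise * eps[in_block]
                )
                latent = base_mu + config.latent_sd * z
                if treated and f > 0:
                    latent = latent.copy()
                    latent[depleted_mask] -= config.depletion_log_units * f
                    latent[boosted_mask] += math.log1p(config.effect_dominance) * f
                p = np.exp(latent - latent.max())
                p /= p.sum()
                count_cols.append(rng.multinomial(config.depth, p))
                latent_cols.append(latent)

    counts = np.column_stack(count_cols).astype(np.int64)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = FeatureTable(counts, asv_ids, sample_ids, meta)
    truth = SyntheticTruth(
        block_membership={asv_ids[i]: int(block_of[i]) for i in range(n)},
        effect_trajectory=trajectory,
        depleted_asvs=[asv_ids[i] for i in np.sort(depleted)],
        boosted_asvs=[asv_ids[i] for i in np.sort(boosted)],
        latents=pd.DataFrame(
            np.column_stack(latent_cols), index=asv_ids, columns=sample_ids
        ),
    )
    return table, truth


def generate_pathway_table(
    n_pathways: int,
    n_samples: int,
    planted_clique_size: int,
    rho: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pathway x sample abundances with one mutually correlated block.

    The first ``planted_clique_size`` pathways share an exchangeable
    latent correlation ``rho``; the rest are independent. Values are
    latent-normal shifted positive, so pairwise Pearson r matches the
    latent correlation exactly in expectation.
    """
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    if n_pathways <= 0:
        raise ConfigurationError("n_pathways must be positive")
    if planted_clique_size > n_pathways:
        raise ConfigurationError("planted clique larger than n_pathways")
    if not 0 <= rho < 1:
        raise ConfigurationError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    shared = rng.normal(0.0, 1.0, size=n_samples)
    eps = rng.normal(0.0, 1.0, size=(n_pathways, n_samples))
    values = eps.copy()
    values[:planted_clique_size] = (
        math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps[:planted_clique_size]
    )
    values += 10.0  # positive abundances; Pearson unaffected by the shift
    ids = [f"pathway{i + 1:03d}" for i in range(n_pathways)]
    cols = [f"S{j + 1:03d}" for j in range(n_samples)]
    return pd.DataFrame(values, index=ids, columns=cols)
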
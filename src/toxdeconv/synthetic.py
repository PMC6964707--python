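"""Synthetic paired in vivo / in vitro studies with known ground truth.

The generator states a small but structurally faithful world:

* every compound has an *environmental* profile W_env (the untreated organ
  state; log-normal across genes, values scattered around 1 like
  normalized intensity ratios) and a *drug* profile W_drug equal to W_env
  with a fraction of differentially expressed (DE) genes shifted up or
  down multiplicatively;
* in vivo treated samples are convex mixtures
  h_env * W_env + h_drug * W_drug (h_env drawn per sample, h columns sum
  to one) times multiplicative log-normal noise -- a two-factor system;
* in vivo controls are W_env times noise (pure environmental state);
* in vitro treated samples are the *inverse* affine image of the drug
  profile, (W_drug - intercept) / slope, times noise -- a one-factor
  system whose regression against the recovered drug component should
  return (slope, intercept);
* in vitro controls are the inverse affine image of W_env times noise.

At study level one shared environmental baseline (with small per-compound
jitter) ties the compounds together, and compounds come in related pairs
sharing a configurable fraction of their DE genes so the pairwise Dice
matrices have non-degenerate structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import (
    CompoundDataset,
    DoseLevel,
    ExpressionMatrix,
    SampleMeta,
    System,
)
from .errors import ConfigError

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticStudy", "generate_compound", "generate_study"]


@dataclass
class SyntheticConfig:
    """Stated world of the generator.

    Defaults follow the replicate design of the source data (3 in vivo /
    2 in vitro biological replicates, matched controls) and an affine
    in vitro <-> drug-component link with slope 0.86 and intercept 0.31.
    """

    n_genes: int = 2000
    n_compounds: int = 20
    n_replicates_invivo: int = 3
    n_replicates_invitro: int = 2
    n_controls: int = 3
    frac_de_genes: float = 0.1
    effect_size: float = 4.0
    noise_sd: float = 0.05
    env_animal_sd: float = 0.1
    env_weight_range: tuple[float, float] = (0.4, 0.8)
    ivive_slope: float = 0.86
    ivive_intercept: float = 0.31
    de_overlap: tuple[float, float] = (0.2, 0.9)
    baseline_sigma: float = 0.5
    compound_jitter_sd: float = 0.1
    detection_floor: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.frac_de_genes < 1:
            raise ConfigError("frac_de_genes must lie in (0, 1)")
        lo, hi = self.env_weight_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("env_weight_range must be an interval within (0, 1)")
        if np.isscalar(self.de_overlap):
            self.de_overlap = (float(self.de_overlap), float(self.de_overlap))
        o_lo, o_hi = self.de_overlap
        if not (0 <= o_lo <= o_hi <= 1):
            raise ConfigError("de_overlap must be a sub-interval of [0, 1]")
        if self.effect_size <= 0 or self.noise_sd < 0:
            raise ConfigError("effect_size must be > 0 and noise_sd >= 0")
        if self.ivive_slope <= 0:
            raise ConfigError("ivive_slope must be > 0")
        for name in (
            "n_genes",
            "n_compounds",
            "n_replicates_invivo",
            "n_replicates_invitro",
            "n_controls",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de_genes * self.n_genes))


@dataclass
class GroundTruth:
    """True components, weights and DE genes of one synthetic compound."""

    compound: str
    W_env_true: np.ndarray = field(repr=False)
    W_drug_true: np.ndarray = field(repr=False)
    H_true: np.ndarray = field(repr=False)
    de_genes_up: list[str]
    de_genes_down: list[str]


@dataclass
class SyntheticStudy:
    """Generated multi-compound study: matrices, metadata and truths."""

    expr_invivo: ExpressionMatrix
    meta_invivo: list[SampleMeta]
    expr_invitro: ExpressionMatrix
    meta_invitro: list[SampleMeta]
    truths: dict[str, GroundTruth]
    config: SyntheticConfig


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sd, size=shape))


def generate_compound(
    config: SyntheticConfig,
    compound_id: str,
    rng_state: int | np.random.Generator | None = None,
    *,
    baseline: np.ndarray | None = None,
    de_up: np.ndarray | None = None,
    de_down: np.ndarray | None = None,
) -> tuple[CompoundDataset, CompoundDataset, GroundTruth]:
    """One compound's paired in vivo / in vitro datasets plus ground truth.

    ``baseline`` and the DE gene index arrays are injected by
    :func:`generate_study` to share structure across compounds; standalone
    calls draw them fresh.
    """
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state if rng_state is not None else config.seed)
    )
    m = config.n_genes
    genes = _gene_ids(m)

    if baseline is None:
        baseline = rng.lognormal(0.0, config.baseline_sigma, size=m)
    W_env = baseline * _noise(rng, m, config.compound_jitter_sd)

    n_de = config.n_de
    if de_up is None or de_down is None:
        de = rng.choice(m, size=n_de, replace=False)
        de_up, de_down = de[: n_de // 2], de[n_de // 2 :]
    W_drug = W_env.copy()
    W_drug[de_up] *= config.effect_size
    W_drug[de_down] /= config.effect_size

    lo, hi = config.env_weight_range
    h_env = rng.uniform(lo, hi, size=config.n_replicates_invivo)
    H_true = np.vstack([h_env, 1.0 - h_env])
    # each animal carries its own environmental state (per-sample jitter of
    # the env profile); cultures are homogeneous so in vitro gets none
    env_treated = W_env[:, None] * _noise(
        rng, (m, config.n_replicates_invivo), config.env_animal_sd
    )
    vivo_treated = (
        env_treated * h_env[None, :] + W_drug[:, None] * (1.0 - h_env)[None, :]
    ) * _noise(rng, (m, config.n_replicates_invivo), config.noise_sd)
    env_controls = W_env[:, None] * _noise(
        rng, (m, config.n_controls), config.env_animal_sd
    )
    vivo_controls = env_controls * _noise(rng, (m, config.n_controls), config.noise_sd)

    # inverse affine link, floored at a small detection limit (ratio data
    # never reaches exact zero; keeps control means positive for FC)
    A, B = config.ivive_slope, config.ivive_intercept
    x_drug = np.maximum((W_drug - B) / A, config.detection_floor)
    x_env = np.maximum((W_env - B) / A, config.detection_floor)
    vitro_treated = x_drug[:, None] * _noise(
        rng, (m, config.n_replicates_invitro), config.noise_sd
    )
    vitro_controls = x_env[:, None] * _noise(
        rng, (m, config.n_replicates_invitro), config.noise_sd
    )

    def _expr(values: np.ndarray, tag: str) -> ExpressionMatrix:
        ids = [f"{compound_id}_{tag}{j + 1}" for j in range(values.shape[1])]
        return ExpressionMatrix(genes, ids, values)

    ds_vivo = CompoundDataset(
        compound=compound_id,
        treated=_expr(vivo_treated, "vivo_t"),
        controls=_expr(vivo_controls, "vivo_c"),
        system=System.IN_VIVO_SINGLE,
    )
    ds_vitro = CompoundDataset(
        compound=compound_id,
        treated=_expr(vitro_treated, "vitro_t"),
        controls=_expr(vitro_controls, "vitro_c"),
        system=System.IN_VITRO,
    )
    truth = GroundTruth(
        compound=compound_id,
        W_env_true=W_env,
        W_drug_true=W_drug,
        H_true=H_true,
        de_genes_up=[genes[i] for i in np.sort(de_up)],
        de_genes_down=[genes[i] for i in np.sort(de_down)],
    )
    return ds_vivo, ds_vitro, truth


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Multi-compound study over a shared gene universe.

    Relatedness forms a chain: compound i shares a fraction of its DE genes
    with compound i-1, the fraction drawn per pair from
    ``config.de_overlap``. The chain yields a continuum of pairwise
    similarities (strong first-order, weaker second-order overlaps) so the
    Dice matrices straddle the PRank cut-off instead of saturating.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_genes
    genes = _gene_ids(m)
    baseline = rng.lognormal(0.0, config.baseline_sigma, size=m)
    n_de = config.n_de
    n_up = n_de // 2
    n_down = n_de - n_up
    o_lo, o_hi = config.de_overlap

    width = len(str(config.n_compounds))
    names = [f"C{i + 1:0{width}d}" for i in range(config.n_compounds)]

    vivo_ds: list[CompoundDataset] = []
    vitro_ds: list[CompoundDataset] = []
    truths: dict[str, GroundTruth] = {}
    prev_up = prev_down = None
    for i, name in enumerate(names):
        if prev_up is None:
            de = rng.choice(m, size=n_de, replace=False)
            de_up, de_down = de[:n_up], de[n_up:]
        else:
            frac = rng.uniform(o_lo, o_hi)
            keep_up = int(round(frac * n_up))
            keep_down = int(round(frac * n_down))
            taken = set(prev_up.tolist()) | set(prev_down.tolist())
            pool = np.array([g for g in range(m) if g not in taken])
            fresh = rng.choice(pool, size=(n_up - keep_up) + (n_down - keep_down), replace=False)
            de_up = np.concatenate(
                [rng.choice(prev_up, size=keep_up, replace=False), fresh[: n_up - keep_up]]
            ).astype(int)
            de_down = np.concatenate(
                [rng.choice(prev_down, size=keep_down, replace=False), fresh[n_up - keep_up :]]
            ).astype(int)
        prev_up, prev_down = np.asarray(de_up), np.asarray(de_down)
        dv, dt, truth = generate_compound(
            config, name, rng, baseline=baseline, de_up=prev_up, de_down=prev_down
        )
        vivo_ds.append(dv)
        vitro_ds.append(dt)
        truths[name] = truth

    def _concat(
        datasets: list[CompoundDataset], system: System, time_label: str
    ) -> tuple[ExpressionMatrix, list[SampleMeta]]:
        cols, ids, meta = [], [], []
        for ds in datasets:
            for expr, is_ctrl in ((ds.treated, False), (ds.controls, True)):
                for j, sid in enumerate(expr.sample_ids):
                    cols.append(expr.values[:, j])
                    ids.append(sid)
                    meta.append(
                        SampleMeta(
                            sample_id=sid,
                            compound=ds.compound,
                            system=system,
                            dose_level=DoseLevel.CONTROL if is_ctrl else DoseLevel.HIGH,
                            time_label=time_label,
                            replicate=j + 1,
                            is_control=is_ctrl,
                        )
                    )
        return ExpressionMatrix(genes, ids, np.column_stack(cols)), meta

    expr_vivo, meta_vivo = _concat(vivo_ds, System.IN_VIVO_SINGLE, "24h")
    expr_vitro, meta_vitro = _concat(vitro_ds, System.IN_VITRO, "24h")
    return SyntheticStudy(
        expr_invivo=expr_vivo,
        meta_invivo=meta_vivo,
        expr_invitro=expr_vitro,
        meta_invitro=meta_vitro,
        truths=truths,
        config=config,
    )
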
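"""Synthetic inputs with planted, recoverable structure.

Three generators emulate the statistical shape of the study's inputs:

* ``generate_fos`` — an animal x brain-region intensity table. Intensities
  are log-normal; each sickness condition elevates (or suppresses) a small
  planted set of regions by a known effect, expressed in standard-deviation
  units on the log scale. Deliberately confusable condition pairs
  (STAg/DSS, LPS/pIC) share half of their planted regions.
* ``generate_usv`` — a call x acoustic-feature table with per-condition
  mean shifts, exponential call onsets, and a duration distribution that
  straddles the 5 ms detection floor.
* ``generate_spatial`` — per-cell 2-D maps for a treated and a control
  condition in which "focal" genes are elevated only inside a disc,
  "broad" genes are elevated everywhere, and "null" genes are unchanged,
  plus companion per-cell-type differential-expression tables computed
  from the generated counts.

Every generator is bit-reproducible under a fixed seed and returns a
ground-truth record alongside the data so downstream recovery can be
scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import substream

DEFAULT_CONDITIONS = ("Saline", "LPS", "pIC", "PLA2", "STAg", "DSS")
DEFAULT_CONFUSABLE = (("STAg", "DSS"), ("LPS", "pIC"))


# ---------------------------------------------------------------------------
# FOS intensity matrices


def default_planted_map(
    conditions=DEFAULT_CONDITIONS,
    n_regions: int = 641,
    regions_per_condition: int = 10,
    effect: float = 2.0,
    n_suppressed: int = 2,
    confusable_pairs=DEFAULT_CONFUSABLE,
    shared_fraction: float = 0.5,
) -> dict[str, dict[int, float]]:
    """Deterministic planted map: each non-control condition gets a block of
    informative regions; confusable pairs share ``shared_fraction`` of theirs.

    A few regions per condition carry negative effects (suppression), since
    reduced regional activity can be as state-predictive as induction.
    """
    planted: dict[str, dict[int, float]] = {c: {} for c in conditions}
    control = conditions[0]
    cursor = 0
    n_shared = int(round(shared_fraction * regions_per_condition))
    in_pair = {c: p for p in confusable_pairs for c in p}
    done_pairs = set()
    for cond in conditions:
        if cond == control:
            continue
        pair = in_pair.get(cond)
        if pair is not None and pair in done_pairs:
            continue
        members = [c for c in (pair or (cond,)) if c in conditions]
        if pair is not None:
            done_pairs.add(pair)
            shared = list(range(cursor, cursor + n_shared))
            cursor += n_shared
            for c in members:
                own = list(range(cursor, cursor + (regions_per_condition - n_shared)))
                cursor += regions_per_condition - n_shared
                idx = shared + own
                for r, region in enumerate(idx):
                    sign = -1.0 if r >= regions_per_condition - n_suppressed else 1.0
                    planted[c][region] = sign * effect
        else:
            idx = list(range(cursor, cursor + regions_per_condition))
            cursor += regions_per_condition
            for r, region in enumerate(idx):
                sign = -1.0 if r >= regions_per_condition - n_suppressed else 1.0
                planted[cond][region] = sign * effect
    if cursor > n_regions:
        raise ValueError("planted map does not fit in n_regions")
    return planted


@dataclass
class FosSimConfig:
    """Study conditions for the FOS intensity generator.

    Effects in ``planted_map`` are in standardized units on the log scale:
    an effect of 2.0 shifts the condition's log-intensity mean by two
    within-condition standard deviations.
    """

    n_animals: int = 48
    n_regions: int = 641
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    sex_labels: tuple[str, ...] = ("male", "female")
    planted_map: dict[str, dict[int, float]] = field(default_factory=default_planted_map)
    confusable_pairs: tuple[tuple[str, str], ...] = DEFAULT_CONFUSABLE
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.5
    noise_sd: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals <= 0 or self.n_regions <= 0:
            raise ValueError("n_animals and n_regions must be positive")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if self.n_animals < len(self.conditions):
            raise ValueError("fewer animals than conditions: a condition would be empty")
        for cond, effects in self.planted_map.items():
            if cond not in self.conditions:
                raise ValueError(f"planted condition {cond!r} not among conditions")
            for region, eff in effects.items():
                if not (0 <= region < self.n_regions):
                    raise ValueError(f"planted region {region} out of range")
                if not np.isfinite(eff):
                    raise ValueError("planted effect sizes must be finite")


@dataclass
class FosGroundTruth:
    planted_map: dict[str, dict[int, float]]
    region_names: list[str]
    config: FosSimConfig

    def planted_regions(self, condition: str | None = None) -> set[str]:
        """Region names planted for one condition, or for any condition."""
        conds = [condition] if condition is not None else list(self.planted_map)
        out: set[str] = set()
        for c in conds:
            out |= {self.region_names[i] for i in self.planted_map.get(c, {})}
        return out

    def to_json(self) -> str:
        payload = {
            "planted_map": {
                c: {self.region_names[i]: e for i, e in m.items()}
                for c, m in self.planted_map.items()
            },
            "config": _config_dict(self.config),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return clean(d)


def generate_fos(
    config: FosSimConfig | None = None, sex: str | None = None
) -> tuple[pd.DataFrame, FosGroundTruth]:
    """One sex stratum of animal x region intensities plus ground truth.

    Rows are animals (stratified as evenly as possible across conditions),
    columns are region intensity columns plus ``condition`` and ``sex``
    label columns. Intensities are strictly positive.
    """
    config = config or FosSimConfig()
    config.validate()
    sex = sex if sex is not None else config.sex_labels[0]
    rng = substream(config.seed, "fos", sex)

    n, p = config.n_animals, config.n_regions
    conds = list(config.conditions)
    # stratified allocation: every condition gets floor(n/k), remainder round-robin
    per = [n // len(conds)] * len(conds)
    for i in range(n % len(conds)):
        per[i] += 1
    labels = np.repeat(conds, per)

    region_names = [f"region_{i:04d}" for i in range(p)]
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=p)
    logx = baseline[None, :] + config.noise_sd * rng.standard_normal((n, p))
    for cond, effects in config.planted_map.items():
        rows = labels == cond
        for region, eff in effects.items():
            logx[rows, region] += eff * config.noise_sd
    table = pd.DataFrame(np.exp(logx), columns=region_names)
    table.insert(0, "condition", labels)
    table.insert(1, "sex", sex)
    table.index.name = "animal"
    truth = FosGroundTruth(
        planted_map={c: dict(m) for c, m in config.planted_map.items()},
        region_names=region_names,
        config=config,
    )
    return table, truth


# ---------------------------------------------------------------------------
# USV acoustic-feature tables


def default_class_shifts(
    conditions=DEFAULT_CONDITIONS, n_acoustic: int = 31, effect: float = 1.2
) -> dict[str, np.ndarray]:
    """Each non-control condition shifts its own block of 5 acoustic features."""
    shifts = {}
    for i, cond in enumerate(conditions):
        v = np.zeros(n_acoustic)
        if i > 0:
            lo = (i - 1) * 5 % n_acoustic
            v[lo : lo + 5] = effect
        shifts[cond] = v
    return shifts


@dataclass
class UsvSimConfig:
    """Study conditions for the synthetic vocalization-feature generator.

    ``n_features`` counts all per-call features including the four temporal
    metrics (inter-call onset differences at lags 1-3 and duration/onset),
    which are computed by :mod:`sickstate.usv` on the generated onsets, so
    the number of drawn acoustic features is ``n_features - 4``.
    """

    n_calls_per_condition: int = 500
    n_features: int = 35
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    class_shift_map: dict[str, np.ndarray] | None = None
    onset_rate: float = 2.0  # calls per second
    duration_mean_ms: float = 30.0
    duration_sd_ms: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_calls_per_condition <= 0:
            raise ValueError("n_calls_per_condition must be positive")
        if self.n_features < 4:
            raise ValueError("need at least 4 features (temporal metrics)")
        if self.onset_rate <= 0 or self.duration_sd_ms < 0:
            raise ValueError("onset_rate must be positive, duration sd non-negative")


def generate_usv(config: UsvSimConfig | None = None) -> pd.DataFrame:
    """Call table: onset (s), duration (ms), acoustic + temporal features,
    condition label. Durations are strictly positive; a tail of the duration
    distribution below 5 ms exercises the short-call filter downstream.
    """
    from . import usv as usv_mod  # temporal metrics live with the protocol

    config = config or UsvSimConfig()
    config.validate()
    rng = substream(config.seed, "usv")
    n_acoustic = config.n_features - 4
    shifts = config.class_shift_map
    if shifts is None:
        shifts = default_class_shifts(config.conditions, n_acoustic)

    frames = []
    for cond in config.conditions:
        m = config.n_calls_per_condition
        gaps = rng.exponential(1.0 / config.onset_rate, size=m)
        onsets = np.cumsum(gaps)
        durations = rng.normal(config.duration_mean_ms, config.duration_sd_ms, size=m)
        durations = np.maximum(durations, 0.1)  # strictly positive floor
        feats = rng.standard_normal((m, n_acoustic))
        shift = np.asarray(shifts.get(cond, np.zeros(n_acoustic)), dtype=float)
        feats = feats + shift[None, :]
        df = pd.DataFrame(feats, columns=[f"feat_{j:02d}" for j in range(n_acoustic)])
        df.insert(0, "onset_s", onsets)
        df.insert(1, "duration_ms", durations)
        tm = usv_mod.temporal_metrics(onsets, durations)
        df = pd.concat([df, tm], axis=1)
        df["condition"] = cond
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Spatial cell maps


@dataclass
class GeneSpec:
    name: str
    pattern: str  # focal | broad | null
    effect: float = 2.0  # log2 fold change for affected cells

    def validate(self) -> None:
        if self.pattern not in {"focal", "broad", "null"}:
            raise ValueError(f"unknown pattern tag {self.pattern!r}")


@dataclass
class SpatialSimConfig:
    n_cells: int = 1500
    arena_size: float = 1000.0  # length units (micrometres)
    genes: tuple[GeneSpec, ...] = (
        GeneSpec("focal_gene", "focal", 3.0),
        GeneSpec("broad_gene", "broad", 3.0),
        GeneSpec("null_gene", "null", 0.0),
    )
    n_cell_types: int = 5
    n_animals_per_condition: int = 3
    focal_radius_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 10:
            raise ValueError("n_cells must be at least 10")
        if self.arena_size <= 0:
            raise ValueError("arena_size must be positive")
        for g in self.genes:
            g.validate()


def generate_spatial(config: SpatialSimConfig | None = None):
    """Treated and control cell maps plus per-cell-type DE tables.

    Returns ``(maps, de_table, truth)`` where ``maps`` is a dict with keys
    ``"treated"`` and ``"control"`` holding :class:`~sickstate.spatial.
    SpatialCellMap` objects, and ``de_table`` has one row per gene x cell
    type with empirical log2 fold change and BH-adjusted Mann-Whitney p.
    """
    from .spatial import SpatialCellMap
    from statsmodels.stats.multitest import multipletests

    config = config or SpatialSimConfig()
    config.validate()
    rng = substream(config.seed, "spatial")
    L = config.arena_size
    center = np.array([L / 2, L / 2])
    radius = config.focal_radius_fraction * L

    maps = {}
    per_cond_expr = {}
    per_cond_types = {}
    for cond in ("control", "treated"):
        n = config.n_cells
        coords = rng.uniform(0, L, size=(n, 2))
        cell_types = rng.integers(0, config.n_cell_types, size=n)
        animals = rng.integers(0, config.n_animals_per_condition, size=n)
        expr = {}
        for g in config.genes:
            base = rng.lognormal(mean=1.0, sigma=0.5, size=n)
            if cond == "treated" and g.pattern != "null":
                if g.pattern == "focal":
                    inside = np.linalg.norm(coords - center, axis=1) <= radius
                    base[inside] *= 2.0**g.effect
                else:  # broad
                    base *= 2.0**g.effect
            expr[g.name] = base
        expression = pd.DataFrame(expr)
        maps[cond] = SpatialCellMap(
            coords=coords,
            expression=expression,
            condition=cond,
            cell_types=np.array([f"type_{t}" for t in cell_types]),
            animals=np.array([f"{cond}_{a}" for a in animals]),
        )
        per_cond_expr[cond] = expression
        per_cond_types[cond] = cell_types

    rows = []
    for g in config.genes:
        for t in range(config.n_cell_types):
            x = per_cond_expr["treated"][g.name][per_cond_types["treated"] == t]
            y = per_cond_expr["control"][g.name][per_cond_types["control"] == t]
            lfc = float(np.log2(x.mean() / y.mean()))
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append({"gene": g.name, "cell_type": f"type_{t}", "log2fc": lfc, "pvalue": p})
    de = pd.DataFrame(rows)
    de["padj"] = multipletests(de["pvalue"], method="fdr_bh")[1]
    truth = {g.name: g.pattern for g in config.genes}
    return maps, de, truth
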
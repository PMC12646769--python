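"""End-to-end pipeline: simulate -> discretize -> classify -> selection ->
energetics -> report.

Everything is driven by a :class:`PipelineConfig` (YAML round-trippable);
all randomness flows from its seeds, so a fixed config reproduces its
output tables byte for byte.  Stage outputs are CSV; the report is
markdown; a JSON manifest records the config hash, seeds and row counts at
every filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import energetics, ssa, synthetic_data, tracks
from .errors import ConfigurationError, WayfarerError
from .rasters import LandscapeStack
from .tracks import STAGE_ACTIVE, STAGE_LOCAL, STAGE_RESIDENT, Track

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and module parameters, with the study defaults."""

    out_dir: str = "pipeline_out"
    seed: int = 1
    # simulation scenario
    n_dispersers: int = 2
    n_residents: int = 3
    n_days: int = 8
    landscape: dict = field(default_factory=dict)  # LandscapeConfig overrides
    walker: dict = field(default_factory=dict)  # WalkerConfig overrides
    hi_res_hours_per_day: float = 4.5
    # discretization / classification
    min_step: float = 10.0  # m
    displacement_radius: float = 50.0  # m
    active_displacement_hi: float = 1500.0  # m
    active_displacement_lo: float = 1200.0  # m
    straightness_min: float = 0.3
    settlement_window_days: int = 14
    settlement_radius: float = 200.0  # m
    # selection
    n_alternatives: int = 20
    variants: tuple = ("within_stage", "vs_resident", "two_level")
    drop_habitats: tuple = ("black_cotton", "bare_soil")
    # energetics
    cot_reference: str = "road"
    cot_mixed: bool = False

    def validate(self) -> None:
        if self.n_alternatives <= 0 or self.min_step < 0:
            raise ConfigurationError("invalid thresholds")
        bad = set(self.variants) - set(ssa.VARIANTS)
        if bad:
            raise ConfigurationError(f"unknown model variants: {sorted(bad)}")

    # -- round-trip ---------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        d["drop_habitats"] = list(self.drop_habitats)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        for key in ("variants", "drop_habitats"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# scenario simulation
# ---------------------------------------------------------------------------

def simulate_scenario(
    config: PipelineConfig,
) -> tuple[LandscapeStack, list[Track]]:
    """Simulate the default synthetic scenario: resident birds plus
    dispersers alternating active/local days, on one shared landscape."""
    lc = synthetic_data.LandscapeConfig(
        seed=config.seed, **config.landscape
    )
    stack = synthetic_data.generate_landscape(lc)
    out: list[Track] = []
    rng = np.random.default_rng(config.seed + 1)
    for i in range(config.n_residents):
        wc = synthetic_data.WalkerConfig(seed=config.seed, **config.walker)
        schedule = [STAGE_RESIDENT] * config.n_days
        tr = synthetic_data.simulate_track(
            stack, wc, schedule,
            individual_id=f"res{i:02d}",
            start_xy=_random_start(rng, stack),
            rng=np.random.default_rng(rng.integers(2**63)),
        )
        out.append(synthetic_data.emit_dual_rate(tr, config.hi_res_hours_per_day))
    for i in range(config.n_dispersers):
        wc = synthetic_data.WalkerConfig(seed=config.seed, **config.walker)
        schedule = [
            STAGE_ACTIVE if d % 3 != 2 else STAGE_LOCAL for d in range(config.n_days)
        ]
        tr = synthetic_data.simulate_track(
            stack, wc, schedule,
            individual_id=f"dis{i:02d}",
            start_xy=_random_start(rng, stack),
            rng=np.random.default_rng(rng.integers(2**63)),
        )
        out.append(synthetic_data.emit_dual_rate(tr, config.hi_res_hours_per_day))
    return stack, out


def _random_start(rng, stack):
    g = stack.grid
    return (
        g.x0 + rng.uniform(0.3, 0.7) * (g.x_max - g.x0),
        g.y_min + rng.uniform(0.3, 0.7) * (g.y_top - g.y_min),
    )


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def classify_tracks(
    track_list: list[Track], config: PipelineConfig
) -> pd.DataFrame:
    """Day summaries + stage classification for every track.

    Individuals whose id starts with 'res' (or with an all-resident true
    stage) are classified on the resident branch; everyone else is
    transient.
    """
    frames = []
    for tr in track_list:
        resident = _is_resident(tr)
        summ = tracks.day_summaries(tr)
        summ = tracks.classify_days(summ, resident=resident)
        summ.insert(0, "individual", tr.individual_id)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)


def _is_resident(tr: Track) -> bool:
    if "true_stage" in tr.df.columns:
        return bool((tr.df["true_stage"] == STAGE_RESIDENT).all())
    return tr.individual_id.startswith("res")


def build_step_table(
    track_list: list[Track], day_classes: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Discretize every track and attach per-day stage labels."""
    frames = []
    counts = dict(n_windows=0, n_candidate_steps=0, n_retained=0)
    for tr in track_list:
        steps = tracks.discretize_5min(tr, min_step=config.min_step)
        for k in counts:
            counts[k] += steps.attrs[k]
        if steps.empty:
            continue
        steps.insert(0, "individual", tr.individual_id)
        cls = day_classes.loc[day_classes["individual"] == tr.individual_id,
                              ["date", "classification"]]
        steps["date"] = steps["t_start"].dt.normalize()
        steps = steps.merge(cls, on="date", how="left")
        steps = steps.rename(columns={"classification": "stage"})
        frames.append(steps)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not out.empty:
        out = out.dropna(subset=["stage"]).reset_index(drop=True)
    out.attrs["counts"] = counts
    return out


def run_selection(
    step_table: pd.DataFrame,
    stack: LandscapeStack,
    config: PipelineConfig,
) -> tuple[dict, pd.DataFrame, dict]:
    """Strata assembly, post-hoc habitat filter and all model variants."""
    dists = ssa.fit_step_distributions(step_table)
    strata = ssa.build_strata(
        step_table, dists, stack, m=config.n_alternatives, seed=config.seed + 17
    )
    filtered = ssa.filter_habitat_posthoc(strata, config.drop_habitats)
    posthoc_counts = filtered.attrs["posthoc_counts"]
    fits = {}
    for variant in config.variants:
        try:
            fits[variant] = ssa.fit_selection(filtered, variant, drop_degenerate=True)
        except WayfarerError as exc:
            log.warning("selection variant '%s' failed: %s", variant, exc)
    return fits, filtered, posthoc_counts


def run_energetics(
    track_list: list[Track],
    day_classes: pd.DataFrame,
    stack: LandscapeStack,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """Displacement/CoT records for all tracks plus per-stage models."""
    frames = []
    counts = dict(displacements=0, mixed_habitat=0, kept=0)
    shared_hmm = energetics.fit_hmm_tracks(track_list, seed=config.seed + 29)
    for tr in track_list:
        cls = day_classes[day_classes["individual"] == tr.individual_id]
        stage_by_date = dict(zip(cls["date"], cls["classification"]))
        rec = energetics.displacement_records(
            tr, stack, stage_by_date, hmm=shared_hmm,
            radius=config.displacement_radius,
        )
        if rec.empty:
            continue
        for k in counts:
            counts[k] += rec.attrs["counts"].get(k, 0)
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not records.empty:
        records = records.dropna(subset=["stage"]).reset_index(drop=True)
    models = (
        energetics.cot_models(records, config.cot_reference, config.cot_mixed)
        if not records.empty else {}
    )
    return records, {"counts": counts, "models": models}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_digest": config.digest(), "seed": config.seed,
                      "counts": {}}

    stage = "simulate"
    try:
        stack, track_list = simulate_scenario(config)
        stack.save(out / "landscape")
        tracks.write_tracks(track_list, out / "tracks.csv")
        manifest["counts"]["raw_fixes"] = int(sum(len(t) for t in track_list))

        stage = "classify-days"
        day_classes = classify_tracks(track_list, config)
        day_classes.to_csv(out / "day_summaries.csv", index=False)
        manifest["counts"]["days"] = int(len(day_classes))
        manifest["counts"]["classified_days"] = int(
            day_classes["classification"].notna().sum()
        )

        stage = "discretize"
        step_table = build_step_table(track_list, day_classes, config)
        step_table.to_csv(out / "steps.csv", index=False)
        manifest["counts"].update(step_table.attrs["counts"])
        manifest["counts"]["staged_steps"] = int(len(step_table))

        stage = "ssa-fit"
        fits, strata, posthoc_counts = run_selection(step_table, stack, config)
        strata.to_csv(out / "strata.csv", index=False)
        manifest["counts"]["posthoc"] = posthoc_counts
        rss_tables = {}
        for variant, fit in fits.items():
            tab = ssa.rss_report(fit)
            tab.to_csv(out / f"selection_{variant}.csv")
            rss_tables[variant] = tab

        stage = "energetics"
        records, energy_info = run_energetics(track_list, day_classes, stack, config)
        records.to_csv(out / "displacements.csv", index=False)
        manifest["counts"]["energetics"] = energy_info["counts"]
        for st, model in energy_info["models"].items():
            model.coefficients.to_csv(out / f"cot_{st}_coefficients.csv", index=False)
            model.contrasts.to_csv(out / f"cot_{st}_contrasts.csv", index=False)

        stage = "report"
        report = render_report(config, manifest, rss_tables, energy_info["models"])
        (out / "report.md").write_text(report)
    except Exception as exc:
        raise WayfarerError(
            f"pipeline stage '{stage}' failed: {exc} (outputs under {out})"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    config.to_yaml(out / "config.yaml")
    return manifest


def report_counts(manifest: dict) -> pd.DataFrame:
    """Filter-funnel table from a pipeline manifest."""
    c = manifest.get("counts", {})
    posthoc = c.get("posthoc", {})
    energ = c.get("energetics", {})
    rows = [
        ("raw GPS fixes", c.get("raw_fixes", 0)),
        ("5-min windows", c.get("n_windows", 0)),
        ("candidate steps", c.get("n_candidate_steps", 0)),
        ("retained steps (>= 10 m)", c.get("n_retained", 0)),
        ("stage-labelled steps", c.get("staged_steps", 0)),
        ("strata before post-hoc filter", posthoc.get("strata_in", 0)),
        ("strata after post-hoc filter", posthoc.get("strata_out", 0)),
        ("net displacements", energ.get("displacements", 0)),
        ("same-habitat displacements", energ.get("kept", 0)),
    ]
    return pd.DataFrame(rows, columns=["stage", "count"])


def render_report(config, manifest, rss_tables, cot_models_by_stage) -> str:
    lines = ["# Pipeline report", "",
             f"Config digest: `{manifest['config_digest']}`; seed {config.seed}.", "",
             "## Filter funnel", ""]
    lines.append(report_counts(manifest).to_markdown(index=False))
    for variant, tab in rss_tables.items():
        lines += ["", f"## Selection model ({variant})", "",
                  tab[["estimate", "se", "p", "rss", "rss_lo", "rss_hi", "stars"]]
                  .round(4).to_markdown()]
    for st, model in cot_models_by_stage.items():
        lines += ["", f"## Cost of transport ({st}, reference={model.reference}, "
                  f"n={model.n})", "",
                  model.coefficients.round(4).to_markdown(index=False),
                  "", "Pairwise contrasts:", "",
                  model.contrasts.round(4).to_markdown(index=False)]
    lines.append("")
    return "\n".join(lines)
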
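"""End-to-end synthetic study: generate a cohort, run every analysis
stage, and emit a report containing the classification confusion matrix,
quantal recovery rates, distance profiles, per-day probabilities, and
the reproduction block of the published connectivity statistics."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity_stats as cstats
from . import ephys_features as ef
from . import mapping as mp
from . import puncta_spatial as ps
from . import synaptic_quantal as sq
from .io import write_json
from .synthetic import (
    FSI_PARAMS,
    NFSI_PARAMS,
    FieldParams,
    ReleaseModelParams,
    TimecourseParams,
    gen_cohort,
    gen_connectivity_field,
    gen_paired_sweeps,
    gen_puncta_cloud,
    gen_timecourse,
)

logger = logging.getLogger("ng2circuit")

__all__ = ["StudyConfig", "validate_config", "run_study", "ValidationError", "StageError"]


class ValidationError(ValueError):
    pass


class StageError(RuntimeError):
    pass


DEFAULT_CONFIG = {
    "seed": 42,
    "cohort": {"n_per_class": 20},
    "quantal": {"n_connections": 8, "n_sweeps": 150,
                "one_site": {"p1": 0.6, "p2": 0.35},
                "two_site": {"p1": 0.9, "p2": 0.45},
                "quantal_size_pa": -7.71, "noise_sd_pa": 1.5},
    "puncta": {"n_pv": 300, "n_nonpv": 300},
    "field": {"n_ng2_maps": 15, "n_pyr_maps": 10, "n_interneurons": 40,
              "p_near": 0.5},
    "timecourse": {"n_cells_per_day": 25},
    "reproduction": {"p_a": 0.43, "p_b": 0.21, "total_pairs": 147,
                     "total_connected": 38,
                     "ci_a": [0.30, 0.57], "ci_b": [0.15, 0.27],
                     "level": 0.90},
}

_REQUIRED_BLOCKS = ("cohort", "quantal", "puncta", "field", "timecourse", "reproduction")


@dataclass
class StudyConfig:
    """Validated study configuration; see ``DEFAULT_CONFIG`` for the schema."""

    data: dict

    @classmethod
    def from_dict(cls, raw: dict | None = None) -> "StudyConfig":
        merged = _merge(DEFAULT_CONFIG, raw or {})
        errors, _ = validate_config(merged)
        if errors:
            raise ValidationError("; ".join(errors))
        return cls(data=merged)

    def __getitem__(self, key):
        return self.data[key]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(raw: dict) -> tuple[list, list]:
    """Returns (errors, warnings); unknown top-level keys are warnings."""
    errors, warnings = [], []
    if "seed" not in raw or raw["seed"] is None:
        errors.append("a seed is required (no silent nondeterminism)")
    for block in _REQUIRED_BLOCKS:
        if block not in raw:
            errors.append(f"missing config block: {block}")
    known = set(_REQUIRED_BLOCKS) | {"seed", "out"}
    for key in raw:
        if key not in known:
            warnings.append(f"unknown config key: {key}")
    cohort = raw.get("cohort", {})
    if cohort.get("n_per_class", 1) < 1:
        errors.append("cohort.n_per_class must be >= 1")
    q = raw.get("quantal", {})
    if q.get("n_sweeps", 100) < 100:
        errors.append("quantal.n_sweeps must be >= 100")
    tc = raw.get("timecourse", {})
    if tc.get("n_cells_per_day", 1) < 1:
        errors.append("timecourse.n_cells_per_day must be >= 1")
    return errors, warnings


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def run_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Run all stages, write per-stage CSV/JSON outputs, return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"seed": seed}

    stages = [
        ("classification", _stage_classification),
        ("quantal", _stage_quantal),
        ("puncta", _stage_puncta),
        ("mapping", _stage_mapping),
        ("timecourse", _stage_timecourse),
        ("reproduction", _stage_reproduction),
    ]
    for i, (name, fn) in enumerate(stages):
        logger.info("stage %s starting", name)
        try:
            summary[name] = fn(config, _stage_rng(seed, i), out)
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc
    write_json(out / "summary.json", summary)
    return summary


def _stage_classification(config: StudyConfig, rng: np.random.Generator, out: Path) -> dict:
    n = config["cohort"]["n_per_class"]
    cohort_seed = int(rng.integers(2**31))
    cohort = gen_cohort(n, cohort_seed)
    rows = []
    for rec, truth in cohort:
        fs = ef.extract_feature_set(rec)
        row = fs.as_dict()
        row["true_label"] = truth["label"]
        row["predicted"] = ef.classify_interneuron(fs)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "features.csv", index=False)
    confusion = pd.crosstab(df["true_label"], df["predicted"]).to_dict()
    accuracy = float((df["true_label"] == df["predicted"]).mean())
    return dict(n_cells=len(df), accuracy=accuracy, confusion=confusion,
                cohort_seed=cohort_seed)


def _stage_quantal(config: StudyConfig, rng: np.random.Generator, out: Path) -> dict:
    q = config["quantal"]
    results = []
    for n_sites, block in ((1, q["one_site"]), (2, q["two_site"])):
        for _ in range(q["n_connections"]):
            params = ReleaseModelParams(
                n_sites=n_sites, p1=block["p1"], p2=block["p2"],
                quantal_size_pa=q["quantal_size_pa"],
                noise_sd_pa=q["noise_sd_pa"], n_sweeps=q["n_sweeps"])
            sweeps, _ = gen_paired_sweeps(params, rng=rng)
            sd = float(np.median([sq.noise_sd(s) for s in sweeps]))
            events = [sq.detect_psc(s, sd) for s in sweeps]
            res = sq.classify_release_sites(events)
            summ = sq.summarize_connection(events)
            results.append(dict(
                true_sites=n_sites, called_sites=res.n_sites,
                quantal_size_pa=res.quantal_size_pa,
                ppr=summ.ppr, p1=summ.p1, p2=summ.p2,
                mean_psc1_nf=summ.mean_without_failures_pa[0]))
    df = pd.DataFrame(results)
    df.to_csv(out / "quantal.csv", index=False)
    correct = df["called_sites"] == df["true_sites"]
    qs = df.loc[(df.true_sites == 1) & correct, "quantal_size_pa"]
    return dict(
        n_connections=len(df),
        recovery_rate=float(correct.mean()),
        mean_quantal_size_pa=(float(qs.mean()) if len(qs) else None),
    )


def _stage_puncta(config: StudyConfig, rng: np.random.Generator, out: Path) -> dict:
    p = config["puncta"]
    cloud, morph, truth = gen_puncta_cloud(p["n_pv"], p["n_nonpv"], rng=rng)
    contacts = ps.classify_contacts(cloud, morph)
    contacts.to_csv(out / "puncta_contacts.csv", index=False)
    branch = contacts[contacts.compartment == "branch"]
    dist = ps.distance_distributions(
        branch.loc[branch.pv, "distance_um"], branch.loc[~branch.pv, "distance_um"])
    dens = ps.shell_density_profile(cloud)
    dens.to_csv(out / "puncta_density.csv", index=False)
    return dict(
        mean_branch_distance_pv_um=dist["mean_pv_plus"],
        mean_branch_distance_nonpv_um=dist["mean_pv_minus"],
        ks_p_value=dist["ks_p_value"],
    )


def _stage_mapping(config: StudyConfig, rng: np.random.Generator, out: Path) -> dict:
    f = config["field"]
    result = {}
    for kind, n_maps in (("NG2", f["n_ng2_maps"]), ("pyramidal", f["n_pyr_maps"])):
        params = FieldParams(
            target_kind=kind, n_interneurons=f["n_interneurons"], p_near=f["p_near"],
            radius_um=100.0)
        maps = [gen_connectivity_field(params, rng=rng) for _ in range(n_maps)]
        profile, summ = mp.distance_profile(maps)
        profile.to_csv(out / f"distance_profile_{kind}.csv", index=False)
        result[kind] = dict(
            max_connected_um=summ["max_connected_um"],
            ks_p_value=summ.get("ks_p_value"),
            notice=summ.get("ks_notice"),
        )
    return result


def _stage_timecourse(config: StudyConfig, rng: np.random.Generator, out: Path) -> dict:
    n = config["timecourse"]["n_cells_per_day"]
    records = gen_timecourse(TimecourseParams(), n, rng=rng)
    records.to_csv(out / "timecourse.csv", index=False)
    records["group"] = "interneuron"
    table = cstats.probability_by_group(records)
    table.to_csv(out / "probability_by_day.csv", index=False)
    correlations = {}
    for day, sub in records.groupby("day"):
        r, p = cstats.pearson_correlation(sub["na_density_pa_pf"], sub["spont_frequency_hz"])
        correlations[int(day)] = dict(r=r, p=p)
    peak_day = int(table.loc[table["p"].idxmax(), "day"])
    return dict(peak_day=peak_day, correlations=correlations,
                probabilities={int(r.day): r.p for r in table.itertuples()})


def _stage_reproduction(config: StudyConfig, rng: np.random.Generator, out: Path) -> dict:
    r = config["reproduction"]
    table = cstats.reconstruct_contingency(
        r["p_a"], r["p_b"], r["total_pairs"], r["total_connected"],
        ci_a_rounded=tuple(r["ci_a"]), ci_b_rounded=tuple(r["ci_b"]),
        level=r["level"])
    chi2, df, p = cstats.pearson_chi2(table)
    ci_a = cstats.wilson_interval(table.connected_a, table.n_a, r["level"])
    ci_b = cstats.wilson_interval(table.connected_b, table.n_b, r["level"])
    different, alpha_bound = cstats.interval_overlap_test(ci_a, ci_b)
    block = dict(
        table=dict(connected_a=table.connected_a, unconnected_a=table.unconnected_a,
                   connected_b=table.connected_b, unconnected_b=table.unconnected_b),
        chi2=cstats.round_half_up(chi2, 2), chi2_p=p,
        ci_a=list(ci_a.rounded()), ci_b=list(ci_b.rounded()),
        intervals_disjoint=different, alpha_bound=alpha_bound,
    )
    write_json(out / "reproduction.json", block)
    return block
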
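"""CSV/YAML schemas, pipeline orchestration and Table-style reporting.

Schemas (UTF-8, decimal point, units embedded in column names):

* ``samples.csv``:    sample_id, campaign, parameter, count, m_g, m_P_g, m_I_g, m_F_g
* ``duplicates.csv``: sample_id, parameter, count_rep1, count_rep2
* ``spikes.csv``:     sample_id, parameter, polymer, added, recovered
* balance config (YAML/JSON): max_admissible_error_g, repeatability_sd_g, repeatability_df
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import (
    DuplicateSet,
    RandomEffects,
    SpikeSet,
    SystematicEffects,
    estimate_random_effects,
    estimate_systematic_effects,
)
from .gravimetry import BalanceSpec, DryWeightRecord, PortionMass
from .montecarlo import (
    ContaminationResult,
    MCSettings,
    SampleRecord,
    campaign_mean,
    compare,
    simulate_contamination,
)

logger = logging.getLogger("mpuncert")

SAMPLE_COLUMNS = ["sample_id", "campaign", "parameter", "count", "m_g", "m_P_g", "m_I_g", "m_F_g"]
DUPLICATE_COLUMNS = ["sample_id", "parameter", "count_rep1", "count_rep2"]
SPIKE_COLUMNS = ["sample_id", "parameter", "polymer", "added", "recovered"]


class ParseError(ValueError):
    """A schema violation naming the offending file, row and column."""


def _fail(path, row, column, message) -> None:
    raise ParseError(f"{path}: row {row}, column {column!r}: {message}")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _natural(value, path, row, column) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        f = float("nan")
    if not np.isfinite(f) or f < 0 or f != int(f):
        _fail(path, row, column, f"counts must be natural numbers, got {value!r}")
    return int(f)


def _positive_float(value, path, row, column) -> float:
    try:
        f = float(value)
    except (TypeError, ValueError):
        f = float("nan")
    if not np.isfinite(f) or f <= 0:
        _fail(path, row, column, f"expected a positive number, got {value!r}")
    return f


def read_samples(path) -> list[SampleRecord]:
    """Read and validate monitoring samples; errors name the row and column."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SAMPLE_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after header
        count = _natural(row["count"], path, rownum, "count")
        masses = {c: _positive_float(row[c], path, rownum, c) for c in ("m_g", "m_P_g", "m_I_g", "m_F_g")}
        if not (masses["m_P_g"] < masses["m_F_g"] <= masses["m_I_g"]):
            _fail(path, rownum, "m_F_g", "gravimetric invariant violated: need m_P_g < m_F_g <= m_I_g")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                campaign=str(row["campaign"]),
                parameter=str(row["parameter"]),
                count=count,
                portion=PortionMass(masses["m_g"]),
                dry_record=DryWeightRecord(masses["m_P_g"], masses["m_I_g"], masses["m_F_g"]),
            )
        )
    return records


def write_samples(records: list[SampleRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id, "campaign": r.campaign, "parameter": r.parameter,
            "count": r.count, "m_g": repr(r.portion.nominal_mass),
            "m_P_g": repr(r.dry_record.m_petri), "m_I_g": repr(r.dry_record.m_initial_gross),
            "m_F_g": repr(r.dry_record.m_final_gross),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)


def read_duplicates(path) -> dict[str, DuplicateSet]:
    """Read duplicate count pairs, grouped per parameter."""
    df = pd.read_csv(path)
    _require_columns(df, DUPLICATE_COLUMNS, path)
    for idx, row in df.iterrows():
        for col in ("count_rep1", "count_rep2"):
            _natural(row[col], path, idx + 2, col)
    out = {}
    for param, grp in df.groupby("parameter", sort=True):
        pairs = list(zip(grp["count_rep1"].astype(int), grp["count_rep2"].astype(int)))
        out[str(param)] = DuplicateSet(pairs, parameter_label=str(param))
    return out


def write_duplicates(sets: dict[str, DuplicateSet], path) -> None:
    rows = [
        {"sample_id": f"D{i + 1:02d}", "parameter": label, "count_rep1": a, "count_rep2": b}
        for label, ds in sets.items()
        for i, (a, b) in enumerate(ds.pairs)
    ]
    pd.DataFrame(rows, columns=DUPLICATE_COLUMNS).to_csv(path, index=False)


def read_spikes(path) -> dict[str, SpikeSet]:
    """Read spike recoveries, grouped per parameter.

    For a combined parameter spanning several polymers the rows simply
    concatenate: M is then spike samples x polymers, each unit normalised to
    its own ``added`` count (which must be constant within a parameter).
    """
    df = pd.read_csv(path)
    _require_columns(df, SPIKE_COLUMNS, path)
    out = {}
    for param, grp in df.groupby("parameter", sort=True):
        added = {_natural(a, path, i + 2, "added") for i, a in zip(grp.index, grp["added"])}
        if len(added) != 1:
            raise ParseError(f"{path}: parameter {param!r} mixes different 'added' counts {sorted(added)}")
        recovered = [
            _natural(n, path, i + 2, "recovered") for i, n in zip(grp.index, grp["recovered"])
        ]
        out[str(param)] = SpikeSet(recovered, added.pop(), parameter_label=str(param))
    return out


def write_spikes(sets: dict[str, SpikeSet], path) -> None:
    rows = [
        {"sample_id": f"F{i + 1:02d}", "parameter": label, "polymer": label,
         "added": ss.added_per_unit, "recovered": n}
        for label, ss in sets.items()
        for i, n in enumerate(ss.recovered)
    ]
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def read_balance(path) -> BalanceSpec:
    """Balance config from YAML or JSON: max_admissible_error_g, repeatability_sd_g, repeatability_df."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping of balance keys")
    try:
        return BalanceSpec(
            max_admissible_error=float(data["max_admissible_error_g"]),
            repeatability_sd=float(data["repeatability_sd_g"]),
            repeatability_df=int(data.get("repeatability_df", 9)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing balance key {exc}") from exc


@dataclass(frozen=True)
class StudyConfig:
    """Everything one monitoring study needs: balance, MC settings, data paths."""

    balance: BalanceSpec
    settings: MCSettings
    samples_path: str
    duplicates_path: str
    spikes_path: str
    parameters: tuple = ()

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        base = Path(path).parent
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        balance = BalanceSpec(
            max_admissible_error=float(data["balance"]["max_admissible_error_g"]),
            repeatability_sd=float(data["balance"]["repeatability_sd_g"]),
            repeatability_df=int(data["balance"].get("repeatability_df", 9)),
        )
        mc = data.get("monte_carlo", {})
        settings = MCSettings(
            n_draws=int(mc.get("n_draws", 49_999)),
            seed=int(mc.get("seed", 0)),
            lower_percentile=float(mc.get("lower_percentile", 0.5)),
            upper_percentile=float(mc.get("upper_percentile", 99.5)),
            mode_bins=int(mc.get("mode_bins", 200)),
        )
        paths = data["paths"]
        return cls(
            balance=balance,
            settings=settings,
            samples_path=str(base / paths["samples"]),
            duplicates_path=str(base / paths["duplicates"]),
            spikes_path=str(base / paths["spikes"]),
            parameters=tuple(data.get("parameters", ())),
        )


def estimate_all_effects(
    duplicates: dict[str, DuplicateSet], spikes: dict[str, SpikeSet]
) -> dict[str, tuple[RandomEffects, SystematicEffects]]:
    """Per-parameter (random, systematic) effects from the validation data."""
    out = {}
    for param in sorted(set(duplicates) & set(spikes)):
        out[param] = (estimate_random_effects(duplicates[param]), estimate_systematic_effects(spikes[param]))
    return out


def run_pipeline(config: StudyConfig, out_dir) -> dict[str, Path]:
    """Run the full study: estimate effects, simulate every sample, compare.

    Writes ``results.csv`` (full precision), ``comparisons.csv`` (all
    within-campaign pairs of the same parameter), ``report.txt`` (Table-style
    ``mode; [P0.5; P99.5]`` lines, integer kg^-1, including per-campaign
    means) and ``manifest.json`` (seed, draws, version) under ``out_dir``.
    Each sample gets its own substream spawned deterministically from the
    configured seed, so results are byte-identical across reruns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    samples = read_samples(config.samples_path)
    effects = estimate_all_effects(read_duplicates(config.duplicates_path), read_spikes(config.spikes_path))
    missing = sorted({s.parameter for s in samples} - set(effects))
    if missing:
        raise ParseError(
            f"parameter(s) {missing} appear in samples but have no duplicate/spike validation data; "
            "add them to both validation files or drop the samples"
        )
    logger.info("loaded %d samples, effects for %s (%.2f s)", len(samples), sorted(effects), time.perf_counter() - t0)

    root_seq = np.random.SeedSequence(config.settings.seed)
    results: list[ContaminationResult] = []
    rows = []
    for sample, child in zip(samples, root_seq.spawn(len(samples))):
        re_, se_ = effects[sample.parameter]
        res = simulate_contamination(
            sample, re_, se_, config.balance, config.settings, rng=np.random.default_rng(child)
        )
        results.append(res)
        rows.append(
            {
                "sample_id": sample.sample_id, "campaign": sample.campaign,
                "parameter": sample.parameter, "mode_kg": repr(res.mode),
                "p0.5_kg": repr(res.p_lower), "p99.5_kg": repr(res.p_upper),
                "n_draws": config.settings.n_draws, "seed": config.settings.seed,
            }
        )
    results_path = out_dir / "results.csv"
    pd.DataFrame(rows).to_csv(results_path, index=False)
    logger.info("simulated %d samples (%.2f s)", len(results), time.perf_counter() - t0)

    comp_rows = []
    keyed = list(zip(samples, results))
    for (sa, ra), (sb, rb) in itertools.combinations(keyed, 2):
        if sa.campaign != sb.campaign or sa.parameter != sb.parameter:
            continue
        outcome = compare(ra, rb, config.settings)
        comp_rows.append(
            {
                "id_a": sa.sample_id, "id_b": sb.sample_id, "campaign": sa.campaign,
                "parameter": sa.parameter, "verdict": outcome.verdict,
                "diff_p0.5": repr(outcome.diff_p_lower), "diff_p99.5": repr(outcome.diff_p_upper),
            }
        )
    comparisons_path = out_dir / "comparisons.csv"
    pd.DataFrame(
        comp_rows,
        columns=["id_a", "id_b", "campaign", "parameter", "verdict", "diff_p0.5", "diff_p99.5"],
    ).to_csv(comparisons_path, index=False)

    report_lines = ["Microplastic contamination (kg^-1), as mode; [P0.5; P99.5]", ""]
    for sample, res in keyed:
        report_lines.append(f"{sample.campaign} {sample.sample_id} {sample.parameter}: {res.format()}")
    report_lines.append("")
    report_lines.append("Campaign means:")
    by_group: dict[tuple, list[ContaminationResult]] = {}
    for sample, res in keyed:
        by_group.setdefault((sample.campaign, sample.parameter), []).append(res)
    for (camp, param), grp in sorted(by_group.items()):
        mean_res = campaign_mean(grp, config.settings)
        report_lines.append(f"{camp} {param}: {mean_res.format()}")
    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n", encoding="utf-8")

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {
                "package": "mpuncert", "version": __version__,
                "seed": config.settings.seed, "n_draws": config.settings.n_draws,
                "lower_percentile": config.settings.lower_percentile,
                "upper_percentile": config.settings.upper_percentile,
                "mode_bins": config.settings.mode_bins,
                "samples": str(config.samples_path),
                "duplicates": str(config.duplicates_path),
                "spikes": str(config.spikes_path),
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    logger.info("pipeline complete (%.2f s)", time.perf_counter() - t0)
    return {
        "results": results_path, "comparisons": comparisons_path,
        "report": report_path, "manifest": manifest_path,
    }
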
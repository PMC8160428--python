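"""One-command orchestration of the full analysis.

Stages run in dependency order: (simulate | ingest) -> species germination
profiles -> abundance responses and community-weighted means -> functional
diversity -> species-level beta regressions -> community-level mixed models
with likelihood-ratio tests and Tukey letters -> PCA. Every stage writes a
tidy CSV; undefined values are empty cells with reason codes carried in
sibling columns, never sentinel numbers. A JSON manifest records the config,
seed, input digests and outputs, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .types import AnalysisConfig, NitrogenLevel, TemperatureCondition, ValidationError
from .io import read_trials, read_quadrats, write_table
from .simulate import (
    SimulationConfig,
    draw_species_pool,
    pool_to_frame,
    simulate_quadrats,
    simulate_trials,
)
from .traits import build_profiles, profiles_to_frame
from .community import (
    CWM_VARIABLES,
    compute_abundance_responses,
    responses_to_frame,
    summaries_to_frame,
    summarize_communities,
)
from .fd import build_trait_space, fd_all, fd_results_to_frame
from .betareg import fit_all_species_regressions, fits_to_frame
from .lmm import term_tests
from .pca import pca_cwm
from .tukey import tukey_groups

__all__ = ["RunManifest", "run_pipeline", "report", "load_config", "trials_to_frame",
           "quadrats_to_frame"]

#: Community responses analysed per temperature (two-factor models).
TEMP_STRUCTURED = {
    "CWM_GP": [f"CWM_GP_{t}" for t in (5, 10, 15, 20, 25)],
    "CWM_GR": [f"CWM_GR_{t}" for t in (5, 10, 20, 25)],
    "CWM_O": [f"CWM_O_{t}" for t in (5, 10, 15, 20, 25)],
    "CWM_P": [f"CWM_P_{t}" for t in (5, 10, 15, 20, 25)],
}
#: Community responses analysed marginally (one-factor models).
SINGLE_RESPONSES = ["CWM_BTN", "CWM_R_5_25", "CWM_R_wc", "FRic", "FEve", "FDiv"]


@dataclasses.dataclass
class RunManifest:
    config: dict
    rng_seed: int
    input_digests: dict[str, str]
    outputs: list[str]
    stage_seconds: dict[str, float]
    package_version: str
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_config(path: str) -> tuple[AnalysisConfig, SimulationConfig]:
    """Read a YAML config with optional ``analysis:`` and ``simulation:``
    sections mirroring the two config dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    analysis = AnalysisConfig(**(raw.get("analysis") or {}))
    sim_raw = raw.get("simulation") or {}
    if "coupling" in sim_raw and sim_raw["coupling"] is None:
        sim_raw["coupling"] = {}
    simulation = SimulationConfig(**sim_raw)
    return analysis, simulation


def trials_to_frame(trials) -> pd.DataFrame:
    rows = []
    for t in trials:
        for day, count in enumerate(t.daily_counts, start=1):
            if count > 0:
                rows.append(
                    {
                        "species_id": t.species_id,
                        "condition": t.condition.name,
                        "storage": t.storage.name,
                        "replicate": t.replicate_id,
                        "n_sown": t.n_sown,
                        "day": day,
                        "count": count,
                    }
                )
        if t.total_germinated == 0:
            # keep fully ungerminated trials visible with an explicit zero row
            rows.append(
                {
                    "species_id": t.species_id,
                    "condition": t.condition.name,
                    "storage": t.storage.name,
                    "replicate": t.replicate_id,
                    "n_sown": t.n_sown,
                    "day": 1,
                    "count": 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species_id", "condition", "storage", "replicate", "n_sown", "day", "count"],
    )


def quadrats_to_frame(quadrats) -> pd.DataFrame:
    rows = [
        {"block": q.block_id, "n_level": q.n_level.name, "species_id": sp, "count": n}
        for q in quadrats
        for sp, n in q.species_counts.items()
    ]
    return pd.DataFrame(rows, columns=["block", "n_level", "species_id", "count"])


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _community_table(summaries, fd_results) -> pd.DataFrame:
    cwm = summaries_to_frame(summaries)
    fd = fd_results_to_frame(fd_results)
    merged = cwm.merge(fd, on=["block", "n_level"], how="left")
    renames = {f"CWM_{v}": f"CWM_{v}" for v in CWM_VARIABLES}
    return merged.rename(columns=renames)


def community_model_tests(community: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """LRT chi-square tests per community response.

    Per-temperature responses (GP, GR, O, P families) are melted to long
    format and tested for temperature, fertilization and their interaction;
    scalar responses (BTN, the regime responses, the FD indices) are tested
    for fertilization only.
    """
    rows = []
    for family, cols in TEMP_STRUCTURED.items():
        present = [c for c in cols if c in community.columns]
        long = community.melt(
            id_vars=["block", "n_level"],
            value_vars=present,
            var_name="temperature",
            value_name="value",
        ).dropna(subset=["value"])
        long["temperature"] = long["temperature"].str.rsplit("_", n=1).str[-1]
        try:
            tests = term_tests(
                long, "value", ["temperature", "n_level"], interaction=True, block="block"
            )
        except ValidationError as exc:
            rows.append({"response": family, "term": "error", "chi2": np.nan,
                         "df": np.nan, "p": np.nan, "note": str(exc)})
            continue
        for t in tests:
            term = {"temperature": "temperature", "n_level": "fertilization",
                    "temperature:n_level": "temperature:fertilization"}.get(t.term, t.term)
            rows.append({"response": family, "term": term, "chi2": t.chi2,
                         "df": t.df, "p": t.p, "note": ""})
    for resp in SINGLE_RESPONSES:
        if resp not in community.columns:
            continue
        sub = community[["block", "n_level", resp]].dropna()
        try:
            tests = term_tests(sub, resp, ["n_level"], block="block")
        except ValidationError as exc:
            rows.append({"response": resp, "term": "error", "chi2": np.nan,
                         "df": np.nan, "p": np.nan, "note": str(exc)})
            continue
        for t in tests:
            rows.append({"response": resp, "term": "fertilization", "chi2": t.chi2,
                         "df": t.df, "p": t.p, "note": ""})
    return pd.DataFrame(rows, columns=["response", "term", "chi2", "df", "p", "note"])


def run_pipeline(
    analysis: AnalysisConfig | None = None,
    simulation: SimulationConfig | None = None,
    trials_path: str | None = None,
    quadrats_path: str | None = None,
    out_dir: str = "out",
    seed: int | None = None,
) -> RunManifest:
    """Execute every stage and write all result tables plus manifest.json.

    Either a :class:`SimulationConfig` (synthetic run) or both input paths
    (ingest run) must be provided. ``seed`` overrides the simulation config's
    seed so CLI ``--seed`` wins.
    """
    analysis = analysis or AnalysisConfig()
    ingest = trials_path is not None or quadrats_path is not None
    if ingest and (trials_path is None or quadrats_path is None):
        raise ValidationError("ingest runs need both --trials and --quadrats")
    if not ingest and simulation is None:
        simulation = SimulationConfig()
    if seed is not None and simulation is not None:
        simulation = dataclasses.replace(simulation, rng_seed=int(seed))

    os.makedirs(out_dir, exist_ok=True)
    timings: dict[str, float] = {}
    warnings: list[str] = []
    outputs: list[str] = []
    digests: dict[str, str] = {}

    def out(name: str) -> str:
        path = os.path.join(out_dir, name)
        outputs.append(name)
        return path

    t0 = time.perf_counter()
    if ingest:
        trials = read_trials(trials_path, analysis)
        quadrats = read_quadrats(quadrats_path)
        digests["trials"] = _digest(trials_path)
        digests["quadrats"] = _digest(quadrats_path)
    else:
        pool = draw_species_pool(simulation)
        trials = simulate_trials(pool, simulation)
        quadrats = simulate_quadrats(pool, simulation)
        write_table(trials_to_frame(trials), out("trials.csv"))
        write_table(quadrats_to_frame(quadrats), out("quadrats.csv"))
        write_table(pool_to_frame(pool), out("truth.csv"))
    timings["inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    profiles = build_profiles(trials, analysis)
    write_table(profiles_to_frame(profiles), out("profiles.csv"))
    timings["profiles"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    responses = compute_abundance_responses(quadrats, analysis.rf_pooling)
    write_table(responses_to_frame(responses), out("responses.csv"))
    summaries = summarize_communities(quadrats, profiles)
    timings["community_metrics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        space = build_trait_space(profiles, analysis.fd_axes, quadrats)
        fd_results = fd_all(space, quadrats)
        for sp, reason in space.dropped_species:
            warnings.append(f"fd: dropped {sp} ({reason})")
    except ValidationError as exc:
        fd_results = []
        warnings.append(f"fd: skipped ({exc})")
    community = _community_table(summaries, fd_results)
    write_table(community, out("cwm.csv"))
    if fd_results:
        write_table(fd_results_to_frame(fd_results), out("fd.csv"))
    timings["functional_diversity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits, fit_errors = fit_all_species_regressions(
        responses, profiles, analysis.boundary_epsilon
    )
    for name, msg in sorted(fit_errors.items()):
        warnings.append(f"fit-species: {name} skipped ({msg})")
    write_table(fits_to_frame(fits), out("species_fits.csv"))
    timings["species_fits"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    community_tests = community_model_tests(community, analysis.significance_level)
    write_table(community_tests, out("community_fits.csv"))
    timings["community_fits"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cwm_cols = [f"CWM_{v}" for v in CWM_VARIABLES]
    pca_input = community[cwm_cols].dropna()
    if len(pca_input) < len(community):
        warnings.append(
            f"pca: dropped {len(community) - len(pca_input)} quadrat(s) with undefined CWMs"
        )
    try:
        result = pca_cwm(pca_input)
        loadings, scores, var = result.to_frames()
        long = pd.concat(
            [
                var.assign(kind="variance", name="").rename(
                    columns={"variance_explained": "value"}
                )[["kind", "name", "component", "value"]],
                loadings.reset_index(names="name")
                .melt(id_vars="name", var_name="component", value_name="value")
                .assign(kind="loading")[["kind", "name", "component", "value"]],
                scores.assign(
                    name=[
                        f"{b}:{l}"
                        for b, l in zip(
                            community.loc[pca_input.index, "block"],
                            community.loc[pca_input.index, "n_level"],
                        )
                    ]
                )
                .melt(id_vars="name", var_name="component", value_name="value")
                .assign(kind="score")[["kind", "name", "component", "value"]],
            ],
            ignore_index=True,
        )
        write_table(long, out("pca.csv"))
    except ValidationError as exc:
        warnings.append(f"pca: skipped ({exc})")
    timings["pca"] = time.perf_counter() - t0

    manifest = RunManifest(
        config={
            "analysis": dataclasses.asdict(analysis),
            "simulation": dataclasses.asdict(simulation) if simulation else None,
            "trials_path": trials_path,
            "quadrats_path": quadrats_path,
        },
        rng_seed=(simulation.rng_seed if simulation else analysis.rng_seed),
        input_digests=digests,
        outputs=outputs,
        stage_seconds={k: round(v, 6) for k, v in timings.items()},
        package_version=__version__,
        warnings=warnings,
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest


def _fmt(v, nd=3):
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "—"
    return f"{v:.{nd}f}"


def report(out_dir: str, alpha: float = 0.05) -> str:
    """Markdown summary of a completed run, regenerated from its output files.

    Sections: species-level regression table, community LRT table, CWM by
    treatment with Tukey letters, FD by treatment with Tukey letters, and
    PCA variance with top loadings. Deterministic given the output files.
    """
    def path(name):
        return os.path.join(out_dir, name)

    manifest_path = path("manifest.json")
    if not os.path.exists(manifest_path):
        raise ValidationError(f"no manifest.json under {out_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    for name in manifest["outputs"]:
        if not os.path.exists(path(name)):
            raise ValidationError(f"manifest references missing file {name}")

    lines = [
        "# germfilter run report",
        "",
        f"Package version {manifest['package_version']}, seed {manifest['rng_seed']}.",
        "",
    ]

    lines.append("## Species-level beta regressions (index vs transformed R_f)")
    lines.append("")
    if os.path.exists(path("species_fits.csv")):
        fits = pd.read_csv(path("species_fits.csv"))
        lines.append("| predictor | slope | z | p | pseudo-R2 | n |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in fits.iterrows():
            lines.append(
                f"| {r['predictor']} | {_fmt(r['slope'])} | {_fmt(r['z'])} "
                f"| {_fmt(r['p'], 4)} | {_fmt(r['pseudo_r2'])} | {int(r['n_used'])} |"
            )
    else:
        lines.append("skipped")
    lines.append("")

    lines.append("## Community-level likelihood-ratio tests")
    lines.append("")
    if os.path.exists(path("community_fits.csv")):
        tests = pd.read_csv(path("community_fits.csv"))
        lines.append("| response | term | chi2 | df | p |")
        lines.append("|---|---|---|---|---|")
        for _, r in tests.iterrows():
            df_val = "—" if pd.isna(r["df"]) else int(r["df"])
            lines.append(
                f"| {r['response']} | {r['term']} | {_fmt(r['chi2'], 2)} "
                f"| {df_val} | {_fmt(r['p'], 4)} |"
            )
    else:
        lines.append("skipped")
    lines.append("")

    community = pd.read_csv(path("cwm.csv")) if os.path.exists(path("cwm.csv")) else None

    def letter_table(title: str, columns: list[str]):
        lines.append(title)
        lines.append("")
        lines.append("| variable | " + " | ".join(lv.name for lv in NitrogenLevel) + " |")
        lines.append("|---" * (len(NitrogenLevel) + 1) + "|")
        for col in columns:
            if community is None or col not in community.columns:
                continue
            sub = community[["n_level", col]].dropna()
            cells = []
            try:
                res = tukey_groups(sub, alpha=alpha, response=col, factor="n_level")
                for lv in NitrogenLevel:
                    if lv.name in res.means:
                        cells.append(f"{_fmt(res.means[lv.name])} {res.letters[lv.name]}")
                    else:
                        cells.append("—")
            except ValidationError:
                means = sub.groupby("n_level")[col].mean()
                cells = [_fmt(means.get(lv.name)) for lv in NitrogenLevel]
            lines.append(f"| {col} | " + " | ".join(cells) + " |")
        lines.append("")

    if community is not None:
        cwm_cols = [f"CWM_{v}" for v in CWM_VARIABLES]
        letter_table("## Community-weighted means by treatment (Tukey letters)", cwm_cols)
        if "FRic" in community.columns:
            letter_table("## Functional diversity by treatment (Tukey letters)",
                         ["FRic", "FEve", "FDiv"])
        else:
            lines.extend(["## Functional diversity by treatment", "", "skipped", ""])
    else:
        lines.extend(["## Community-weighted means by treatment", "", "skipped", ""])

    lines.append("## PCA of community-weighted means")
    lines.append("")
    if os.path.exists(path("pca.csv")):
        pca_long = pd.read_csv(path("pca.csv"))
        var = pca_long[pca_long["kind"] == "variance"]
        shares = {r["component"]: r["value"] for _, r in var.iterrows()}
        pc12 = [c for c in ("PC1", "PC2") if c in shares]
        lines.append(
            "Variance explained: "
            + ", ".join(f"{c} {shares[c] * 100:.2f}%" for c in pc12)
            + f" (first two PCs {sum(shares[c] for c in pc12) * 100:.2f}%)."
        )
        lines.append("")
        load = pca_long[pca_long["kind"] == "loading"]
        for comp in pc12:
            sub = load[load["component"] == comp].sort_values(
                "value", ascending=False, kind="mergesort"
            )
            top = ", ".join(f"{r['name']} ({r['value']:+.3f})" for _, r in sub.head(3).iterrows())
            bottom = ", ".join(
                f"{r['name']} ({r['value']:+.3f})" for _, r in sub.tail(3).iterrows()
            )
            lines.append(f"- {comp}: strongest positive {top}; strongest negative {bottom}.")
    else:
        lines.append("skipped")
    lines.append("")
    return "\n".join(lines)
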
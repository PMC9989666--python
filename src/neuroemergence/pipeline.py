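"""End-to-end orchestration: cohort -> per-subject measures -> group inference.

The single interchange schema between stages is a tidy long-format table with
columns (subject, group, measure, value).  Measures computed per subject:

* ``capacity``, ``normalized_capacity``, ``downward_causation``,
  ``causal_decoupling``, ``tdmi`` — pairwise causal-emergence quantities
  averaged over region pairs (timeseries required);
* ``hierarchy`` — spatiotemporal hierarchy of intrinsic-driven ignition
  (timeseries required);
* ``avg_controllability``, ``modal_controllability`` — whole-brain network
  controllability (connectome required).

Subjects missing a modality simply have missing rows for the affected
measures.  The model-replication stage builds per-group consensus
connectomes, selects the global coupling G per group, simulates cohorts of
BOLD runs with the dynamic mean-field model and pushes the simulated data
through the identical functional measures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controllability import consensus_connectome, controllability_profile
from .datatypes import RegionalTimeseries, StructuralConnectome
from .dmf import DMFParams, fic_tune, fit_g_to_fcd, select_g_stability, simulate_dmf
from .ignition import bandpass, hierarchy_from_timeseries
from .phid import global_emergence, hrf_deconvolve
from .stats import GroupedMeasure, ancova, one_way_anova, pairwise_posthoc, spearman
from .synthetic_data import SyntheticCohortSpec, generate_var_cohort, write_cohort

logger = logging.getLogger(__name__)

FUNCTIONAL_MEASURES = (
    "capacity",
    "normalized_capacity",
    "downward_causation",
    "causal_decoupling",
    "tdmi",
    "hierarchy",
)
STRUCTURAL_MEASURES = ("avg_controllability", "modal_controllability")


@dataclass
class PipelineConfig:
    lag: int = 1
    method: str = "CCS"  # PID redundancy for emergence capacity
    estimator: str = "discrete"
    hrf_deconvolution: bool = False
    ignition_band: tuple[float, float] = (0.04, 0.07)
    ignition_window: int = 4
    z_threshold: float = 1.0
    n_perm: int = 10000
    covariates: list[str] = field(default_factory=list)
    # model replication
    g_grid: tuple[float, float, float] = (0.1, 2.5, 0.1)  # start, stop, step
    n_sims: int = 10
    sim_duration: float = 480.0  # seconds of simulated BOLD per run
    sim_tr: float = 2.0
    sim_band: tuple[float, float] = (0.008, 0.09)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**loaded)
        for name in ("ignition_band", "g_grid", "sim_band"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)

    def add_file(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[path.name] = digest

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


# ---------------------------------------------------------------------------
# subject-level measures


def subject_functional_measures(
    ts: RegionalTimeseries, config: PipelineConfig
) -> dict[str, float]:
    """Emergence and ignition measures from one subject's timeseries."""
    work = hrf_deconvolve(ts) if config.hrf_deconvolution else ts
    result, _ = global_emergence(
        work, lag=config.lag, method=config.method, estimator=config.estimator
    )
    out = {
        "capacity": result.capacity,
        "normalized_capacity": result.normalized_capacity,
        "downward_causation": result.downward_causation,
        "causal_decoupling": result.causal_decoupling,
        "tdmi": result.tdmi,
    }
    try:
        hierarchy, _ = hierarchy_from_timeseries(
            work,
            band=config.ignition_band,
            z_threshold=config.z_threshold,
            window=config.ignition_window,
        )
        out["hierarchy"] = hierarchy
    except ValueError as exc:
        logger.warning("hierarchy unavailable for %s: %s", ts.meta.get("subject_id"), exc)
        out["hierarchy"] = np.nan
    return out


def subject_structural_measures(conn: StructuralConnectome) -> dict[str, float]:
    profile = controllability_profile(conn)
    return {
        "avg_controllability": profile.global_average,
        "modal_controllability": profile.global_modal,
    }


def run_subject_measures(
    data: str | Path | tuple,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-subject measure table from a data directory or in-memory cohort.

    ``data`` is either a directory of ``<subject>_timeseries.tsv`` /
    ``<subject>_connectome.tsv`` files with YAML sidecars, or a tuple
    ``(connectomes, timeseries, groups)`` as returned by
    :func:`neuroemergence.synthetic_data.generate_var_cohort` (either list may
    contain None entries for missing modalities).
    """
    config = config or PipelineConfig()
    subjects: dict[str, dict] = {}
    if isinstance(data, (str, Path)):
        subjects = _scan_directory(Path(data))
    else:
        connectomes, series, groups = data
        for k, group in enumerate(groups):
            ts = series[k] if series else None
            conn = connectomes[k] if connectomes else None
            sid = None
            for obj in (ts, conn):
                if obj is not None and obj.meta.get("subject_id"):
                    sid = obj.meta["subject_id"]
                    break
            sid = sid or f"subject_{k:03d}"
            subjects[sid] = {"group": group, "timeseries": ts, "connectome": conn}
    rows = []
    for sid, entry in sorted(subjects.items()):
        group = entry.get("group", "unknown")
        measures: dict[str, float] = {}
        if entry.get("timeseries") is not None:
            measures.update(subject_functional_measures(entry["timeseries"], config))
        if entry.get("connectome") is not None:
            measures.update(subject_structural_measures(entry["connectome"]))
        for name, value in measures.items():
            rows.append({"subject": sid, "group": group, "measure": name, "value": value})
    return pd.DataFrame(rows, columns=["subject", "group", "measure", "value"])


def _scan_directory(data_dir: Path) -> dict[str, dict]:
    if not data_dir.is_dir():
        raise FileNotFoundError(f"data directory {data_dir} does not exist")
    subjects: dict[str, dict] = {}
    for path in sorted(data_dir.glob("*_timeseries.tsv")):
        sid = path.name[: -len("_timeseries.tsv")]
        ts = RegionalTimeseries.load(path)
        subjects.setdefault(sid, {})["timeseries"] = ts
        subjects[sid]["group"] = ts.meta.get("group", "unknown")
    for path in sorted(data_dir.glob("*_connectome.tsv")):
        sid = path.name[: -len("_connectome.tsv")]
        conn = StructuralConnectome.load(path)
        subjects.setdefault(sid, {})["connectome"] = conn
        subjects[sid].setdefault("group", conn.meta.get("group", "unknown"))
    if not subjects:
        raise FileNotFoundError(f"no subject files found under {data_dir}")
    return subjects


# ---------------------------------------------------------------------------
# group-level analysis


def run_group_analysis(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Omnibus + post-hoc tests per measure, and cross-measure correlations.

    Returns a dict with ``omnibus`` (measure -> TestResult), ``posthoc``
    (measure -> DataFrame with BH-FDR adjusted permutation t-tests) and
    ``correlations`` (DataFrame of pairwise Spearman tests across subjects).
    """
    config = config or PipelineConfig()
    wide = table.pivot_table(index=["subject", "group"], columns="measure", values="value")
    wide = wide.reset_index()
    groups_present = sorted(wide["group"].unique())
    report: dict = {"omnibus": {}, "posthoc": {}, "correlations": None, "notes": []}
    measures = [c for c in wide.columns if c not in ("subject", "group")]
    if covariates is not None:
        missing = set(wide["subject"]) - set(covariates.index)
        if missing:
            raise ValueError(f"covariates missing for subjects: {sorted(missing)}")
    for measure in measures:
        sub = wide.dropna(subset=[measure])
        counts = sub.groupby("group").size()
        usable = counts[counts >= 2].index.tolist()
        if len(usable) < 2:
            report["notes"].append(f"{measure}: fewer than 2 groups with n>=2; tests skipped")
            continue
        sub = sub[sub["group"].isin(usable)]
        gm = GroupedMeasure(
            values=sub[measure].to_numpy(),
            group=sub["group"].tolist(),
            covariates=(
                covariates.loc[sub["subject"]].reset_index(drop=True)
                if covariates is not None
                else None
            ),
        )
        if covariates is not None and len(config.covariates or covariates.columns):
            report["omnibus"][measure] = ancova(gm)
        else:
            report["omnibus"][measure] = one_way_anova(gm)
        report["posthoc"][measure] = pairwise_posthoc(
            gm, n_perm=config.n_perm, seed=config.seed
        )
    if len(measures) >= 2:
        rows = []
        for i, m1 in enumerate(measures):
            for m2 in measures[i + 1 :]:
                both = wide.dropna(subset=[m1, m2])
                if len(both) < 3:
                    continue
                res = spearman(both[m1].to_numpy(), both[m2].to_numpy())
                rows.append(
                    {"measure_1": m1, "measure_2": m2, "rho": res.statistic, "p": res.p_value}
                )
        report["correlations"] = pd.DataFrame(rows)
    if len(groups_present) < 2:
        report["notes"].append("single group present; omnibus tests skipped")
    return report


# ---------------------------------------------------------------------------
# model-based replication


def run_model_replication(
    group_connectomes: dict[str, list[StructuralConnectome]],
    config: PipelineConfig | None = None,
    params: DMFParams | None = None,
    empirical_by_group: dict[str, list[RegionalTimeseries]] | None = None,
    g_selection: str = "stability",
) -> dict:
    """Consensus connectome per group -> DMF simulations -> group comparison.

    For each group: build the consensus matrix, select G (by the stability
    criterion, or with ``g_selection="fcd"`` by fitting the group's empirical
    functional connectivity dynamics), FIC-tune, then run ``config.n_sims``
    simulations whose BOLD is band-pass filtered and scored with the same
    emergence and hierarchy measures as empirical data.  Returns the
    per-simulation measure table, the selected G values and the
    group-comparison report.
    """
    config = config or PipelineConfig()
    params = params or DMFParams()
    if config.n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if g_selection not in ("stability", "fcd"):
        raise ValueError(f"unknown g_selection {g_selection!r}")
    if g_selection == "fcd" and not empirical_by_group:
        raise ValueError("g_selection='fcd' requires empirical timeseries per group")
    g_start, g_stop, g_step = config.g_grid
    grid = np.arange(g_start, g_stop + g_step / 2, g_step)
    rows = []
    g_selected: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)
    for group, conns in group_connectomes.items():
        consensus = consensus_connectome(conns)
        if not consensus.weights.any():
            raise ValueError(f"consensus connectome for group {group!r} is empty")
        if g_selection == "fcd":
            g_star, _ = fit_g_to_fcd(
                consensus,
                empirical_by_group[group],
                grid,
                n_sims=1,
                params=params,
                duration=min(config.sim_duration, 240.0),
                band=config.sim_band,
                seed=config.seed,
            )
        else:
            g_star = select_g_stability(consensus, grid=grid, params=params, seed=config.seed)
        g_selected[group] = g_star
        J, _ = fic_tune(consensus, g_star, params, seed=config.seed)
        p = replace(params, G=g_star, J=J)
        for k in range(config.n_sims):
            sim = simulate_dmf(
                consensus,
                p,
                duration=config.sim_duration,
                seed=int(rng.integers(0, 2**31 - 1)),
                tr=config.sim_tr,
            )
            bold = sim.bold - sim.bold.mean(axis=1, keepdims=True)
            bold = bandpass(bold, config.sim_tr, config.sim_band)
            ts = RegionalTimeseries(
                data=bold,
                tr=config.sim_tr,
                labels=list(consensus.labels),
                meta={"group": group, "subject_id": f"{group}_sim{k:02d}"},
            )
            measures = subject_functional_measures(ts, config)
            for name, value in measures.items():
                rows.append(
                    {
                        "subject": f"{group}_sim{k:02d}",
                        "group": group,
                        "measure": name,
                        "value": value,
                    }
                )
    table = pd.DataFrame(rows, columns=["subject", "group", "measure", "value"])
    report = run_group_analysis(table, config)
    return {"table": table, "g_selected": g_selected, "report": report}


# ---------------------------------------------------------------------------
# convenience: full synthetic run


def run_synthetic_study(
    spec: SyntheticCohortSpec | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate a synthetic cohort, score subjects and run the group analysis."""
    spec = spec or SyntheticCohortSpec()
    config = config or PipelineConfig()
    cohort = generate_var_cohort(spec)
    if out_dir is not None:
        write_cohort(out_dir, *cohort)
    table = run_subject_measures(cohort, config)
    report = run_group_analysis(table, config)
    manifest = RunManifest(
        config={"spec": asdict_safe(spec), "pipeline": asdict_safe(config)},
        seed=spec.seed,
        version=__version__,
    )
    return {"table": table, "report": report, "manifest": manifest, "cohort": cohort}


def asdict_safe(obj) -> dict:
    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return clean(asdict(obj))


def report_to_text(report: dict) -> str:
    """Human-readable summary of a group-analysis report."""
    lines = []
    for measure, res in report.get("omnibus", {}).items():
        df = res.df if res.df is not None else ""
        lines.append(f"{measure}: F{df} = {res.statistic:.3f}, p = {res.p_value:.4g}")
        posthoc = report.get("posthoc", {}).get(measure)
        if posthoc is not None:
            for _, row in posthoc.iterrows():
                lines.append(
                    f"    {row['comparison']}: t = {row['t']:.3f}, "
                    f"adj. p = {row['adjusted_p']:.4g}, d = {row['cohens_d']:.3f}"
                )
    corr = report.get("correlations")
    if corr is not None and len(corr):
        lines.append("cross-measure Spearman correlations:")
        for _, row in corr.iterrows():
            lines.append(
                f"    {row['measure_1']} ~ {row['measure_2']}: "
                f"rho = {row['rho']:.3f}, p = {row['p']:.4g}"
            )
    for note in report.get("notes", []):
        lines.append(f"note: {note}")
    return "\n".join(lines)


def save_report(report: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    omnibus_rows = [
        {
            "measure": m,
            "statistic": r.statistic,
            "df": json.dumps(r.df),
            "p": r.p_value,
        }
        for m, r in report.get("omnibus", {}).items()
    ]
    pd.DataFrame(omnibus_rows).to_csv(out_dir / "omnibus.tsv", sep="\t", index=False)
    posthoc_frames = []
    for measure, frame in report.get("posthoc", {}).items():
        frame = frame.copy()
        frame.insert(0, "measure", measure)
        posthoc_frames.append(frame)
    if posthoc_frames:
        pd.concat(posthoc_frames).to_csv(out_dir / "posthoc.tsv", sep="\t", index=False)
    corr = report.get("correlations")
    if corr is not None:
        corr.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    (out_dir / "summary.txt").write_text(report_to_text(report) + "\n")
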
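"""Synthetic cohorts with known ground truth, plus the packaged demographics table.

The restricted patient data cannot be redistributed, so every downstream stage
is exercised on synthetic cohorts: per-subject structural connectomes with a
planted group-wise lesion, and coupled stochastic timeseries generated from
them.  Three groups are emulated (healthy controls and two patient severities,
MCS and UWS analogues).

The lesion model has four ingredients, all monotone in severity:

* multiplicative *attenuation* of all edge weights (global loss of streamline
  count);
* random *edge dropout* (complete loss of individual connections);
* weakening of a shared rank-one *hub backbone* (hub connections are
  preferentially vulnerable to severe injury);
* increased *edge-weight disorder* (surviving connection weights become more
  random after diffuse injury).

The last two flatten the adjacency spectrum and are what lowers modal
controllability in the patient analogues; pure uniform attenuation provably
cannot do that under the sigma_max+1 normalization used downstream.

Timeseries are drawn from a stable first-order vector-autoregressive process
whose coupling matrix derives from the subject's connectome.  The process is
simulated at a sub-TR step (TR/4) and decimated to TR, so that the planted
coupling is visible inside the 0.04-0.07 Hz band used by the ignition
analysis.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import RegionalTimeseries, StructuralConnectome

GROUPS = ("control", "MCS", "UWS")

#: weight magnitude emulating deterministic-tractography streamline counts
STREAMLINE_SCALE = 500.0

#: spread of the fixed population hub profile (log-scale)
HUB_PROFILE_SIGMA = 0.5

#: subject-level log-normal jitter applied to the hub profile
HUB_JITTER = 0.25


class FixtureIntegrityError(RuntimeError):
    """Raised when the packaged demographics fixture does not match its contract."""


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # control | MCS | UWS
    sex: str | None = None
    age: int | None = None
    aetiology: str | None = None
    crsr: int | None = None
    scan: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.age is not None and self.age <= 0:
            raise ValueError("age must be positive")
        if self.crsr is not None and not (0 <= self.crsr <= 23):
            raise ValueError("CRS-R score must lie in [0, 23]")
        if self.group == "control" and (self.aetiology is not None or self.crsr is not None):
            raise ValueError("controls carry no aetiology or CRS-R score")


@dataclass
class CohortTable:
    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_id values must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def filter(self, **kwargs) -> "CohortTable":
        """Subset by exact field values, e.g. ``filter(group="UWS")``."""
        recs = self.records
        for key, val in kwargs.items():
            recs = [r for r in recs if getattr(r, key) == val]
        return CohortTable(records=list(recs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "group": [r.group for r in self.records],
                "sex": [r.sex for r in self.records],
                "age": [r.age for r in self.records],
                "aetiology": [r.aetiology for r in self.records],
                "crsr": [r.crsr for r in self.records],
                "scan": [r.scan for r in self.records],
            }
        )


def load_demographics_fixture() -> CohortTable:
    """Load the packaged patient demographics table (22 DOC patients).

    The table lists sex, age, aetiology, diagnosis (MCS/UWS), CRS-R behavioural
    score and diffusion-scan type per patient.  One MCS patient has scan type
    "Not available" (incomplete diffusion acquisition); filtering that row out
    yields the 21 patients with both modalities.
    """
    with importlib.resources.files("neuroemergence.data").joinpath(
        "demographics_doc.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    expected_cols = ["Sex", "Age", "Aetiology", "Diagnosis", "CRS-R Score", "Scan"]
    if list(df.columns) != expected_cols:
        raise FixtureIntegrityError(f"unexpected fixture columns: {list(df.columns)}")
    if len(df) != 22:
        raise FixtureIntegrityError(f"fixture must contain 22 rows, found {len(df)}")
    if sorted(df["Diagnosis"].unique()) != ["MCS", "UWS"]:
        raise FixtureIntegrityError("fixture diagnoses must be MCS and UWS only")
    records = [
        SubjectRecord(
            subject_id=f"patient_{i:02d}",
            group=row["Diagnosis"],
            sex=row["Sex"],
            age=int(row["Age"]),
            aetiology=row["Aetiology"],
            crsr=int(row["CRS-R Score"]),
            scan=row["Scan"],
        )
        for i, row in df.iterrows()
    ]
    return CohortTable(records=records)


@dataclass
class GroupLesion:
    """Severity knobs of the planted group effect (see module docstring)."""

    attenuation: float = 1.0
    edge_dropout: float = 0.0
    hub_exponent: float = 1.0
    weight_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must lie in (0, 1]")
        if not 0 <= self.edge_dropout < 1:
            raise ValueError("edge_dropout must lie in [0, 1)")


DEFAULT_LESIONS: dict[str, GroupLesion] = {
    "control": GroupLesion(1.0, 0.0, hub_exponent=1.0, weight_sigma=0.5),
    "MCS": GroupLesion(0.7, 0.1, hub_exponent=0.5, weight_sigma=0.75),
    "UWS": GroupLesion(0.4, 0.2, hub_exponent=0.0, weight_sigma=1.0),
}


@dataclass
class SyntheticCohortSpec:
    """Study conditions of the synthetic cohort.

    Defaults mirror the analysed empirical groups: 18 controls, 11 MCS and 10
    UWS analogues, TR = 2 s, 300 BOLD volumes.
    """

    n_regions: int = 60
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 18, "MCS": 11, "UWS": 10}
    )
    n_timepoints: int = 300
    tr: float = 2.0
    lesions: dict[str, GroupLesion] = field(default_factory=lambda: dict(DEFAULT_LESIONS))
    density: float = 0.3
    coupling_scale: float = 0.95
    noise_sd: float = 1.0
    substeps: int = 4  # VAR steps per TR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.coupling_scale < 0:
            raise ValueError("coupling_scale must be non-negative")


def hub_profile(n_regions: int, sigma: float = HUB_PROFILE_SIGMA) -> np.ndarray:
    """Fixed population hub-propensity profile (log-normal quantiles).

    The same regions are hubs in every subject, as in real cohorts where hub
    architecture is an atlas-level property rather than a per-subject draw.
    """
    return np.exp(sigma * norm.ppf((np.arange(n_regions) + 0.5) / n_regions))


def generate_connectome(
    n_regions: int,
    density: float,
    seed: int | np.random.Generator,
    attenuation: float = 1.0,
    edge_dropout: float = 0.0,
    *,
    hub_exponent: float = 1.0,
    weight_sigma: float = 0.5,
    labels: list[str] | None = None,
) -> StructuralConnectome:
    """Draw a synthetic streamline-count connectome.

    Edges are Bernoulli(density) on the upper triangle, thinned by
    Bernoulli(edge_dropout); weights are heavy-tailed positive
    (log-normal x hub backbone x streamline scale), finally multiplied by
    ``attenuation``.  The result is exactly symmetric with zero diagonal.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1] (empty graphs not allowed)")
    if not 0 < attenuation <= 1:
        raise ValueError("attenuation must lie in (0, 1]")
    if not 0 <= edge_dropout < 1:
        raise ValueError("edge_dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    s = hub_profile(n_regions) * np.exp(rng.normal(0.0, HUB_JITTER, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    n_edges = len(iu[0])
    present = rng.random(n_edges) < density
    kept = rng.random(n_edges) >= edge_dropout
    w = (
        STREAMLINE_SCALE
        * np.exp(rng.normal(0.0, weight_sigma, n_edges))
        * (s[iu[0]] * s[iu[1]]) ** hub_exponent
    )
    w = w * present * kept * attenuation
    weights = np.zeros((n_regions, n_regions))
    weights[iu] = w
    weights = weights + weights.T
    return StructuralConnectome(
        weights=weights,
        labels=labels or [],
        meta={
            "density": float(density),
            "attenuation": float(attenuation),
            "edge_dropout": float(edge_dropout),
            "hub_exponent": float(hub_exponent),
            "weight_sigma": float(weight_sigma),
        },
    )


def coupling_matrix(
    connectome: StructuralConnectome, coupling_scale: float, attenuation: float = 1.0
) -> np.ndarray:
    """Build the VAR(1) coupling matrix W from a connectome.

    W is the adjacency matrix normalized by its largest singular value and
    scaled so its spectral radius equals ``coupling_scale * attenuation``,
    capped at 0.95 to guarantee stability.  Scaling by the group attenuation
    here (rather than relying on attenuated weights, which the singular-value
    normalization would cancel) is what plants the ordering of effective
    coupling control > MCS > UWS.
    """
    A = connectome.weights
    sigma_max = np.linalg.norm(A, 2)
    if sigma_max == 0:
        return np.zeros_like(A)
    rho = min(coupling_scale * attenuation, 0.95)
    W = (rho / sigma_max) * A
    # symmetric: spectral radius equals the largest singular value
    assert np.linalg.norm(W, 2) <= 0.95 + 1e-9, "unstable coupling matrix"
    return W


def simulate_var(
    W: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    substeps: int = 4,
    burn_in: int = 50,
) -> np.ndarray:
    """Simulate x(t+1) = W x(t) + eps at a sub-TR step and decimate to TR."""
    n = W.shape[0]
    total = (n_timepoints + burn_in) * substeps
    noise = rng.normal(0.0, noise_sd, size=(total, n))
    X = np.empty((n, total))
    x = noise[0].copy()
    for t in range(total):
        x = W @ x + noise[t]
        X[:, t] = x
    return X[:, burn_in * substeps :: substeps]


def generate_var_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[StructuralConnectome], list[RegionalTimeseries], list[str]]:
    """Generate per-subject connectomes, coupled timeseries and group labels.

    Per subject: a connectome with the group lesion applied, then a stable
    VAR(1) timeseries whose coupling matrix has spectral radius
    coupling_scale x group attenuation (capped at 0.95).  Output is fully
    reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    connectomes: list[StructuralConnectome] = []
    series: list[RegionalTimeseries] = []
    groups: list[str] = []
    for group in GROUPS:
        n_subj = spec.n_subjects_per_group.get(group, 0)
        lesion = spec.lesions[group]
        for k in range(n_subj):
            conn_seed = rng.integers(0, 2**31 - 1)
            conn = generate_connectome(
                spec.n_regions,
                spec.density,
                int(conn_seed),
                attenuation=lesion.attenuation,
                edge_dropout=lesion.edge_dropout,
                hub_exponent=lesion.hub_exponent,
                weight_sigma=lesion.weight_sigma,
            )
            conn.meta["group"] = group
            conn.meta["subject_id"] = f"{group}_{k:02d}"
            W = coupling_matrix(conn, spec.coupling_scale, lesion.attenuation)
            data = simulate_var(
                W, spec.n_timepoints, rng, noise_sd=spec.noise_sd, substeps=spec.substeps
            )
            ts = RegionalTimeseries(
                data=data,
                tr=spec.tr,
                labels=list(conn.labels),
                meta={"group": group, "subject_id": f"{group}_{k:02d}"},
            )
            connectomes.append(conn)
            series.append(ts)
            groups.append(group)
    return connectomes, series, groups


def write_cohort(
    out_dir: str | Path,
    connectomes: list[StructuralConnectome],
    series: list[RegionalTimeseries],
    groups: list[str],
) -> None:
    """Write a cohort as delimited matrices with YAML sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for conn, ts, group in zip(connectomes, series, groups):
        sid = ts.meta.get("subject_id", "subject")
        conn.save(out_dir / f"{sid}_connectome.tsv")
        ts.save(out_dir / f"{sid}_timeseries.tsv")
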
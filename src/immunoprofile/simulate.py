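"""Synthetic cohort generator.

Generates participant metadata and a participants x markers matrix with the
statistical structure the downstream analysis assumes: assay-family blocks
with a one-factor-per-block latent correlation structure (a single
"coordination strength" knob per HIV group), group- and severity-specific
log-scale mean shifts, covariate confounding, and MCAR missingness.

Marker log-magnitudes follow

    log y = mu_marker + delta(group, severity) + X beta + lambda_block f + eps

with lambda_block = sqrt(rho_group) and Var(eps) = (1 - rho_group) sigma^2 so
that markers in the same block have correlation rho_group and marginal SD
sigma. Markers flagged ``log_transform`` are stored as exp(log y) (strictly
positive magnitudes); unflagged markers (functional-antibody percent
readouts) are stored on a percent-like scale 50 + 10 * log y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimulationConfig, ConfigurationError, DEFAULT_FAMILIES, SEVERITIES

__all__ = ["Cohort", "generate_cohort", "apply_positivity", "trio_scenario"]


@dataclass
class Cohort:
    """Participants x markers matrix joined to participant and marker metadata.

    Attributes
    ----------
    metadata : pandas.DataFrame
        One row per participant (index ``participant_id``): ``hiv_status``
        (PLWH/PWOH), ``severity``, ``age``, ``sex``, ``region``, ``smoking``,
        ``days_since_dx``.
    markers : pandas.DataFrame
        Marker magnitudes, same index as ``metadata``; NaN marks missingness.
    marker_meta : pandas.DataFrame
        One row per marker (index ``marker_id``): ``assay_family``,
        ``antigen_class`` (sars2/endemic), ``isotype``, ``log_transform``,
        ``has_response_call``.
    responses : pandas.DataFrame or None
        Optional binary positivity calls for markers with response calls.
    """

    metadata: pd.DataFrame
    markers: pd.DataFrame
    marker_meta: pd.DataFrame
    responses: pd.DataFrame | None = None
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if not self.metadata.index.equals(self.markers.index):
            raise ValueError("metadata and markers must share the participant index")
        if list(self.markers.columns) != list(self.marker_meta.index):
            raise ValueError("markers columns must match marker_meta index")

    @property
    def n_participants(self) -> int:
        return len(self.metadata)

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    def subset(self, mask) -> "Cohort":
        """Row-subset by a boolean mask or index array over participants."""
        return Cohort(
            self.metadata.loc[mask].copy(),
            self.markers.loc[mask].copy(),
            self.marker_meta.copy(),
            None if self.responses is None else self.responses.loc[mask].copy(),
            self.config,
        )

    def design_matrix(self, covariates) -> pd.DataFrame:
        """Numeric covariate columns (sex/region/smoking dummy-coded)."""
        md = self.metadata
        cols = {}
        for c in covariates:
            if c == "sex_male":
                cols[c] = (md["sex"] == "male").astype(float)
            elif c == "region_us":
                cols[c] = (md["region"] == "US").astype(float)
            elif c == "smoking":
                cols[c] = (md["smoking"] == "yes").astype(float)
            else:
                cols[c] = md[c].astype(float)
        return pd.DataFrame(cols, index=md.index)

    def to_csv(self, directory) -> None:
        """Write the metadata / marker-matrix / marker-metadata CSV trio
        plus a JSON sidecar echoing the generating config and seed."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(d / "metadata.csv")
        self.markers.to_csv(d / "markers.csv")
        self.marker_meta.to_csv(d / "marker_meta.csv")
        if self.responses is not None:
            self.responses.to_csv(d / "responses.csv")
        sidecar = {"config": None if self.config is None else self.config.to_dict()}
        (d / "cohort.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read_csv(cls, directory) -> "Cohort":
        d = Path(directory)
        metadata = pd.read_csv(d / "metadata.csv", index_col=0)
        markers = pd.read_csv(d / "markers.csv", index_col=0)
        markers.columns.name = "marker_id"
        marker_meta = pd.read_csv(d / "marker_meta.csv", index_col=0)
        responses = None
        if (d / "responses.csv").exists():
            responses = pd.read_csv(d / "responses.csv", index_col=0)
            responses.columns.name = "marker_id"
        return cls(metadata, markers, marker_meta, responses)


def _marker_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    default_sizes = [n for _, n, *_ in DEFAULT_FAMILIES]
    use_default = list(config.block_sizes) == default_sizes
    k = 0
    for b, size in enumerate(config.block_sizes):
        if use_default:
            fam, _, antigen, isotype, logt, has_call = DEFAULT_FAMILIES[b]
        else:
            fam, antigen, isotype, logt, has_call = f"family_{b}", "sars2", "NA", True, True
        for j in range(size):
            rows.append(
                {
                    "marker_id": f"{fam}_{j + 1}",
                    "assay_family": fam,
                    "antigen_class": antigen,
                    "isotype": isotype,
                    "log_transform": logt,
                    "has_response_call": has_call,
                    "block": b,
                }
            )
            k += 1
    meta = pd.DataFrame(rows).set_index("marker_id")
    assert len(meta) == config.n_markers
    return meta


def _allocate_severity(n: int, props) -> np.ndarray:
    """Largest-remainder allocation of n participants to the 3 strata."""
    raw = np.asarray(props, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(rem):
        counts[order[i]] += 1
    return np.repeat(np.arange(3), counts)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a synthetic cohort; bit-reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta_rows = []
    marker_meta = _marker_metadata(config)
    blocks = marker_meta["block"].to_numpy()
    m = config.n_markers
    n_blocks = len(config.block_sizes)

    log_rows = []
    pid = 0
    for group, n in (("PWOH", config.n_pwoh), ("PLWH", config.n_plwh)):
        sev_idx = _allocate_severity(n, config.severity_props)
        rho = dict(config.within_block_rho)[group]
        lam = np.sqrt(abs(rho)) * np.sign(rho)
        eps_sd = np.sqrt(max(1.0 - abs(rho), 0.0)) * config.marker_sd
        age_mu, age_sd = dict(config.age_mean_sd)[group]
        for i in range(n):
            sev = SEVERITIES[sev_idx[i]]
            age = float(np.clip(rng.normal(age_mu, age_sd), 18, 86))
            sex = "male" if rng.random() < dict(config.male_prob)[group] else "female"
            region = "US" if rng.random() < dict(config.us_prob)[group] else "Peru"
            smoking = "yes" if rng.random() < dict(config.smoking_prob)[group] else "no"
            days = int(rng.integers(config.days_range[0], config.days_range[1] + 1))
            meta_rows.append(
                {
                    "participant_id": f"P{pid:04d}",
                    "hiv_status": group,
                    "severity": sev,
                    "age": age,
                    "sex": sex,
                    "region": region,
                    "smoking": smoking,
                    "days_since_dx": days,
                }
            )
            beta = config.covariate_effects
            xb = (
                beta.get("age", 0.0) * age
                + beta.get("sex_male", 0.0) * (sex == "male")
                + beta.get("region_us", 0.0) * (region == "US")
                + beta.get("smoking", 0.0) * (smoking == "yes")
                + beta.get("days_since_dx", 0.0) * days
            )
            f = rng.normal(size=n_blocks)
            eps = rng.normal(scale=eps_sd, size=m)
            logy = xb + lam * config.marker_sd * f[blocks] + eps
            if group == "PLWH":
                for j, eff in dict(config.marker_effects).items():
                    eff = dict(eff)
                    logy[j] += eff.get("all", 0.0) + eff.get(sev, 0.0)
            log_rows.append(logy)
            pid += 1

    metadata = pd.DataFrame(meta_rows).set_index("participant_id")
    logm = np.asarray(log_rows)
    values = np.where(
        marker_meta["log_transform"].to_numpy()[None, :],
        np.exp(logm),
        50.0 + 10.0 * logm,
    )
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    markers = pd.DataFrame(values, index=metadata.index, columns=marker_meta.index)
    return Cohort(metadata, markers, marker_meta.drop(columns="block"), None, config)


def apply_positivity(cohort: Cohort, cutoffs: Mapping[str, float]) -> Cohort:
    """Attach binary positivity calls: response = 1(magnitude >= cutoff).

    ``cutoffs`` must cover every marker flagged ``has_response_call``;
    magnitudes are left unchanged. Missing magnitudes give missing calls.
    """
    called = cohort.marker_meta.index[cohort.marker_meta["has_response_call"]]
    missing = [mk for mk in called if mk not in cutoffs]
    if missing:
        raise ConfigurationError(f"no cutoff for called markers: {missing[:5]}")
    resp = pd.DataFrame(index=cohort.markers.index, columns=called, dtype=float)
    for mk in called:
        vals = cohort.markers[mk]
        resp[mk] = (vals >= cutoffs[mk]).astype(float).where(vals.notna())
    return Cohort(
        cohort.metadata, cohort.markers, cohort.marker_meta, resp, cohort.config
    )


def trio_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions for the symptomatic-outpatient classification scenario.

    85 PWOH vs 16 PLWH, all symptomatic outpatient; two SARS-CoV-2 B-cell
    markers depressed in PLWH (log-GMR log 0.25) and one endemic-CoV IgG1
    binding marker elevated (log-GMR log 2.84) — the magnitudes of the
    largest adjusted group differences seen for such markers.
    """
    families = [f for f, *_ in DEFAULT_FAMILIES]
    sizes = [n for _, n, *_ in DEFAULT_FAMILIES]
    start = {f: sum(sizes[:i]) for i, f in enumerate(families)}
    bcell1 = start["bcell"]
    bcell2 = start["bcell"] + 1
    endemic = start["igg1_bama_endemic"]
    effects = {
        bcell1: {"symptomatic": float(np.log(0.25))},
        bcell2: {"symptomatic": float(np.log(0.25))},
        endemic: {"symptomatic": float(np.log(2.84))},
    }
    kwargs = dict(
        n_pwoh=85,
        n_plwh=16,
        severity_props=(0.0, 1.0, 0.0),
        marker_effects=effects,
        missing_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
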
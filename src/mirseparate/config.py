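"""Configuration objects for simulation and pipeline runs.

``SimConfig`` pins down every stochastic ingredient of the synthetic-cohort
generator; ``RunConfig`` drives the end-to-end pipeline. Both round-trip
through YAML so a run is fully reproducible from its persisted config.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .datatypes import GROUPS
from .exceptions import ConfigError

# Panel naming: the discriminatory markers reported for this comparison come
# first so default effect tables can address them; the remainder of the
# literature-style custom panel is filled with synthetic placeholder ids.
NAMED_ASSAYS = (
    "miR-29c-3p",
    "miR-425-5p",
    "miR-153-3p",
    "miR-148a-3p",
    "miR-128-3p",
    "miR-223-3p",
    "miR-27a-3p",
    "miR-424-5p",
    "miR-19b-3p",
    "miR-28-5p",
    "miR-30b-5p",
    "miR-185-5p",
    "miR-26a-5p",
    "miR-106a-5p",
    "miR-532-5p",
)


def default_panel(n_assays: int) -> list[str]:
    """Assay ids for an ``n_assays``-plex panel (named markers first)."""
    if n_assays < 1:
        raise ConfigError("panel must contain at least one assay")
    panel = list(NAMED_ASSAYS[:n_assays])
    panel += [f"miR-sim-{i:03d}" for i in range(len(panel) + 1, n_assays + 1)]
    return panel


@dataclass(frozen=True)
class EffectEntry:
    """A planted group shift: ``shift_ct`` cycles added to ``assay`` in ``group``.

    Negative shifts mean higher abundance (fewer cycles). ``fluid`` restricts
    the effect to one biofluid; None applies it to both.
    """

    assay: str
    group: str
    shift_ct: float
    fluid: str | None = None


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-cohort generator settings.

    Defaults emulate the study conditions: a 10/10/11 cohort
    (LRRK2 carriers / sporadic PD / healthy controls), 91-assay custom
    panels in plasma and CSF, Gaussian noise on the Ct scale at the assay,
    plate and well level, a global CSF abundance penalty that censors most
    of the CSF panel at the Ct>40 detection limit, UniSpike 2/3/4/6 spike-in
    controls and a blank well per sample panel.
    """

    n_lrrk2: int = 10
    n_spd: int = 10
    n_hc: int = 11
    n_assays_plasma: int = 91
    n_assays_csf: int = 91
    baseline_ct_mean: float = 33.0  # Ct; extracellular miRNAs sit near the detection limit
    baseline_ct_sd: float = 4.0  # assay-to-assay abundance spread, Ct
    low_abundance_fraction: float = 0.35  # tail of the panel shifted toward the detection limit
    low_abundance_shift: float = 8.0  # Ct penalty for that tail (drives light plasma dropout)
    plate_offset_sd: float = 0.5  # interplate shift, Ct; removed by calibration
    well_noise_sd: float = 0.5  # per-well technical + biological noise, Ct
    effect_table: tuple[EffectEntry, ...] = ()
    csf_shift: float = 10.0  # global CSF abundance penalty, Ct
    censor_ct: float = 40.0  # reactions beyond this cycle are "undetected"
    spikein_ct: dict = field(
        default_factory=lambda: {
            "unispike2": 24.0,
            "unispike3": 21.0,
            "unispike4": 26.0,
            "unispike6": 23.0,
        }
    )
    n_plates: int = 8
    outlier_sample: tuple[str, float] | None = None  # (sample id, sample-wide Ct shift)
    asymptomatic_fraction: float = 0.4  # fraction of LRRK2_MC without symptoms
    csf_detectable_assays: tuple[str, ...] = ()  # exempt from the CSF abundance penalty
    correlated_assays: tuple[str, ...] = ()  # well noise shared between fluids
    cross_fluid_rho: float = 0.5  # noise-sharing coefficient for correlated assays
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lrrk2", "n_spd", "n_hc", "n_assays_plasma", "n_assays_csf", "n_plates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("baseline_ct_sd", "plate_offset_sd", "well_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.asymptomatic_fraction <= 1:
            raise ConfigError("asymptomatic_fraction must lie in [0, 1]")
        if not 0 <= self.low_abundance_fraction <= 1:
            raise ConfigError("low_abundance_fraction must lie in [0, 1]")
        if self.low_abundance_shift < 0:
            raise ConfigError("low_abundance_shift must be >= 0")
        if not 0 <= self.cross_fluid_rho <= 1:
            raise ConfigError("cross_fluid_rho must lie in [0, 1]")
        panel = set(self.panel("plasma")) | set(self.panel("CSF"))
        for entry in self.effect_table:
            if entry.group not in GROUPS:
                raise ConfigError(f"effect_table group {entry.group!r} unknown")
            if entry.assay not in panel:
                raise ConfigError(f"effect_table assay {entry.assay!r} not on the panel")
        for name in ("correlated_assays", "csf_detectable_assays"):
            unknown = set(getattr(self, name)) - panel
            if unknown:
                raise ConfigError(f"{name} not on the panel: {sorted(unknown)}")

    def panel(self, fluid: str) -> list[str]:
        n = self.n_assays_plasma if fluid == "plasma" else self.n_assays_csf
        return default_panel(n)

    @property
    def n_samples(self) -> int:
        return self.n_lrrk2 + self.n_spd + self.n_hc

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_table"] = [list(asdict(e).values()) for e in self.effect_table]
        d["correlated_assays"] = list(self.correlated_assays)
        d["csf_detectable_assays"] = list(self.csf_detectable_assays)
        if self.outlier_sample is not None:
            d["outlier_sample"] = list(self.outlier_sample)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["effect_table"] = tuple(EffectEntry(*row) for row in d.get("effect_table", ()))
        d["correlated_assays"] = tuple(d.get("correlated_assays", ()))
        d["csf_detectable_assays"] = tuple(d.get("csf_detectable_assays", ()))
        if d.get("outlier_sample") is not None:
            sid, shift = d["outlier_sample"]
            d["outlier_sample"] = (str(sid), float(shift))
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings.

    Either ``sim`` (generate a synthetic cohort) or ``plates_path`` +
    ``samples_path`` (read measured plates) supplies the raw data.
    """

    sim: SimConfig | None = None
    plates_path: str | None = None
    samples_path: str | None = None
    censor_ct: float = 40.0
    max_missing: int = 1
    groups: tuple[str, str] = ("LRRK2_MC", "sPD")
    alpha: float = 0.05
    k_consensus: int = 5
    n_models: int = 100
    n_trees: int = 200
    lasso_inner_cv: int = 5
    remove_outliers: bool = False
    include_hc_pca: bool = False
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        if self.sim is None and (self.plates_path is None or self.samples_path is None):
            raise ConfigError("either sim or plates_path+samples_path must be set")
        for g in self.groups:
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim is not None else None
        d["groups"] = list(self.groups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        d["groups"] = tuple(d.get("groups", ("LRRK2_MC", "sPD")))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
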
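"""Run configuration: schema, validation, defaults, reproducibility.

A run is fully described by one YAML (or JSON) document with one block
per taxon group plus light, photosynthesis and sweep settings.  The
schema is strict — unknown keys are rejected by name — and every
output table carries a metadata header (config hash, seed, package
version) sufficient to reproduce it bit for bit.

Default taxon constants follow the standard carbon-volume compilation
used for protist plankton: diatoms sit on a distinctly lower quota
curve (log10 pg C = -0.933 + 0.881 log10 V) than other photosynthetic
protists (log10 pg C = -0.665 + 0.939 log10 V).  The default light
field (i0 = 200, i_sat = 100 umol photons m^-2 s^-1) represents
well-lit, nutrient-replete surface conditions; ``k_att`` and
``p_max_v`` are calibrated once (see
:func:`cfm_diatom.experiments.calibrate_light`) so that the diatom
growth-volume curve peaks at 2 d^-1 at V = 100 um^3.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cell_model import CellParameters, TaxonGroup
from .optics import LightEnvironment, PhotosynthesisParameters

__all__ = [
    "ConfigError",
    "TaxonBlock",
    "LightBlock",
    "PhotosynthesisBlock",
    "SweepBlock",
    "TranscriptBlock",
    "RunConfig",
    "load_config",
    "dump_config",
    "default_config",
    "cell_parameters",
    "metadata_header",
    "rng_for",
]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class TaxonBlock(_StrictModel):
    """Carbon-budget constants for one taxon group (units in comments
    of the shipped default config)."""

    a_c: float = Field(gt=0, description="quota prefactor, pg C at V=1 um^3")
    b_c: float = Field(gt=0, lt=2, description="allometric exponent")
    e_mu: float = Field(default=0.691, ge=0, description="growth respiration, mol C/mol C")
    e_si_per_si: float = Field(default=0.167, ge=0, description="C cost per Si, mol C/mol Si")
    r_sic: float = Field(default=0.0, ge=0, description="cellular Si:C molar ratio")
    e_ex: float = Field(default=0.0, ge=0, description="excreted fraction, mol C/mol C")


class LightBlock(_StrictModel):
    i0: float = Field(default=200.0, ge=0, description="incident irradiance, umol photons m^-2 s^-1")
    k_att: float = Field(default=0.314440, ge=0, description="intracellular attenuation, um^-1")


class PhotosynthesisBlock(_StrictModel):
    p_max_v: float = Field(default=3.02694e-14, gt=0, description="max volumetric fixation, mol C um^-3 d^-1")
    i_sat: float = Field(default=100.0, gt=0, description="saturation irradiance, umol photons m^-2 s^-1")


class SweepBlock(_StrictModel):
    v_min: float = Field(default=1.0, gt=0)
    v_max: float = Field(default=1e8, gt=0)
    n_points: int = Field(default=60, ge=1)
    groups: List[str] = Field(
        default_factory=lambda: ["diatom", "other", "diatom_no_si"]
    )

    @model_validator(mode="after")
    def _ordered(self) -> "SweepBlock":
        if self.v_max < self.v_min:
            raise ValueError("v_max must be >= v_min")
        for g in self.groups:
            TaxonGroup(g)
        return self


class TranscriptBlock(_StrictModel):
    """Synthetic metatranscriptome settings (see transcript_budget)."""

    n_samples: int = Field(default=66, ge=1)
    ribosomal_uplift: float = Field(default=1.5, gt=0)
    cytoskeleton_factor: float = Field(default=0.5, gt=0)
    median_total_reads: float = Field(default=2.0e5, gt=0)
    sigma_log_total: float = Field(default=0.5, ge=0)


def _default_taxa() -> Dict[str, TaxonBlock]:
    return {
        "diatom": TaxonBlock(a_c=10**-0.933, b_c=0.881, r_sic=0.163),
        "other": TaxonBlock(a_c=10**-0.665, b_c=0.939, r_sic=0.0),
    }


class RunConfig(_StrictModel):
    """Validated configuration for a full run."""

    seed: int = 0
    taxa: Dict[str, TaxonBlock] = Field(default_factory=_default_taxa)
    light: LightBlock = Field(default_factory=LightBlock)
    photosynthesis: PhotosynthesisBlock = Field(default_factory=PhotosynthesisBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    transcripts: TranscriptBlock = Field(default_factory=TranscriptBlock)

    @model_validator(mode="after")
    def _known_taxa(self) -> "RunConfig":
        for name in self.taxa:
            try:
                TaxonGroup(name)
            except ValueError:
                raise ValueError(f"unknown taxon group {name!r}") from None
        return self

    # -- convenience accessors -------------------------------------------

    def light_environment(self) -> LightEnvironment:
        return LightEnvironment(i0=self.light.i0, k_att=self.light.k_att)

    def photosynthesis_parameters(self) -> PhotosynthesisParameters:
        return PhotosynthesisParameters(
            p_max_v=self.photosynthesis.p_max_v, i_sat=self.photosynthesis.i_sat
        )

    def volume_grid(self) -> np.ndarray:
        return np.geomspace(self.sweep.v_min, self.sweep.v_max, self.sweep.n_points)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config() -> RunConfig:
    return RunConfig()


def _name_offending_keys(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file.

    An empty file yields all defaults; unknown keys raise
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {_name_offending_keys(exc)}") from exc


def dump_config(config: RunConfig, path=None) -> str:
    """Serialise a config back to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def cell_parameters(config: RunConfig, group) -> CellParameters:
    """Build :class:`CellParameters` for ``group`` from a config.

    The ``diatom_no_si`` counterfactual reuses the diatom block unless
    the config supplies one explicitly.
    """
    group = TaxonGroup(group)
    block = config.taxa.get(group.value)
    if block is None and group is TaxonGroup.DIATOM_NO_SI:
        block = config.taxa.get(TaxonGroup.DIATOM.value)
    if block is None:
        raise ConfigError(f"no parameter block for taxon group {group.value!r}")
    return CellParameters(
        group=group,
        a_c=block.a_c,
        b_c=block.b_c,
        e_mu=block.e_mu,
        e_si_per_si=block.e_si_per_si,
        r_sic=block.r_sic,
        e_ex=block.e_ex,
    )


def metadata_header(config: RunConfig, seed: int | None = None) -> List[str]:
    """Comment lines identifying the run, written atop every output."""
    from . import __version__

    return [
        f"# cfm-diatom v{__version__}",
        f"# config_hash: {config.config_hash()}",
        f"# seed: {config.seed if seed is None else seed}",
    ]


# stable sub-stream ids so modules never share an RNG stream
_RNG_DOMAINS = {"observations": 1, "transcripts": 2}


def rng_for(seed: int, domain: str) -> np.random.Generator:
    """Deterministic per-module RNG derived from the run seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _RNG_DOMAINS[domain]]))
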
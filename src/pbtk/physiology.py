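"""Species- and age-resolved physiology and enzyme ontogeny.

A :class:`PhysiologyProfile` carries the body weight, cardiac output and
per-tissue volumes and blood-flow fractions that instantiate a
perfusion-limited toxicokinetic model.  An :class:`OntogenyTable` maps
(metabolic pathway, age group) to the fraction of adult enzyme activity,
used to scale whole-liver Vmax in paediatric models.

Defaults ship as one versioned YAML file (``data/physiology.yaml``) and
can be overridden by a user file with the same schema.  Every load —
packaged or user-supplied — is validated: volumes must fit in the body
weight and perfused-tissue flow fractions must partition the full
cardiac output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Perfused tissue compartments, in engine order.
TISSUES = (
    "liver",
    "kidney",
    "skin",
    "fat",
    "richly_perfused",
    "slowly_perfused",
)
BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood")
HUMAN_AGE_GROUPS = ("newborn", "3mo", "6mo", "18mo", "adult")


class UnsupportedProfileError(KeyError):
    """Requested (species, age_group) is not a supported combination."""


class MissingOntogenyError(KeyError):
    """No ontogeny entry exists for the requested (pathway, age_group)."""


class ProfileValidationError(ValueError):
    """A physiology profile violates its internal-consistency invariants."""


@dataclass(frozen=True)
class TissueEntry:
    """Volume (L) and blood-flow fraction of one compartment."""

    volume_L: float
    flow_fraction: float | None = None


@dataclass(frozen=True)
class PhysiologyProfile:
    """Validated physiological parameter set for one species/age group.

    Volumes are absolute litres (tissue density 1 kg/L); flow fractions
    are fractions of cardiac output and are carried only by perfused
    tissues, not by the blood compartments.
    """

    species: str
    age_group: str
    body_weight_kg: float
    cardiac_output_L_per_h: float
    tissues: Mapping[str, TissueEntry]

    def __post_init__(self) -> None:
        missing = [t for t in TISSUES + BLOOD_COMPARTMENTS if t not in self.tissues]
        if missing:
            raise ProfileValidationError(
                f"{self.species}/{self.age_group}: missing compartments {missing}"
            )
        if self.body_weight_kg <= 0 or self.cardiac_output_L_per_h <= 0:
            raise ProfileValidationError("body weight and cardiac output must be > 0")
        for name, entry in self.tissues.items():
            if entry.volume_L <= 0:
                raise ProfileValidationError(f"{name}: volume must be > 0")
        total_volume = sum(e.volume_L for e in self.tissues.values())
        if total_volume > 1.05 * self.body_weight_kg:
            raise ProfileValidationError(
                f"tissue volumes ({total_volume:.3f} L) exceed body weight "
                f"({self.body_weight_kg} kg) by more than 5%"
            )
        flow_sum = 0.0
        for name in TISSUES:
            frac = self.tissues[name].flow_fraction
            if frac is None or not 0.0 < frac < 1.0:
                raise ProfileValidationError(
                    f"{name}: flow fraction must lie in (0, 1), got {frac!r}"
                )
            flow_sum += frac
        if abs(flow_sum - 1.0) > 1e-9:
            raise ProfileValidationError(
                f"perfused-tissue flow fractions sum to {flow_sum!r}, expected 1.0"
            )

    def volume(self, compartment: str) -> float:
        return self.tissues[compartment].volume_L

    def flow(self, tissue: str) -> float:
        """Absolute blood flow through a perfused tissue, L/h."""
        frac = self.tissues[tissue].flow_fraction
        if frac is None:
            raise KeyError(f"{tissue} carries no flow fraction")
        return frac * self.cardiac_output_L_per_h

    @property
    def liver_mass_g(self) -> float:
        return self.volume("liver") * 1000.0


@dataclass(frozen=True)
class OntogenyTable:
    """Mapping (pathway, age_group) -> fraction of adult enzyme activity."""

    factors: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for pathway, by_age in self.factors.items():
            for age, f in by_age.items():
                if not 0.0 <= f <= 1.5:
                    raise ProfileValidationError(
                        f"ontogeny factor {pathway}/{age} = {f} outside [0, 1.5]"
                    )
            if "adult" in by_age and by_age["adult"] != 1.0:
                raise ProfileValidationError(
                    f"adult ontogeny factor for {pathway} must be exactly 1.0"
                )

    def factor(self, pathway_name: str, age_group: str) -> float:
        try:
            return self.factors[pathway_name][age_group]
        except KeyError:
            raise MissingOntogenyError(
                f"no ontogeny entry for pathway {pathway_name!r}, "
                f"age group {age_group!r}"
            ) from None


def _default_config_path() -> Path:
    return Path(str(resources.files("pbtk").joinpath("data/physiology.yaml")))


def load_physiology(config_path: str | Path | None = None) -> dict:
    """Parse and validate a physiology/ontogeny config file.

    Returns ``{"profiles": {(species, age): PhysiologyProfile},
    "ontogeny": OntogenyTable}``.
    """
    path = Path(config_path) if config_path is not None else _default_config_path()
    raw = yaml.safe_load(path.read_text())
    profiles: dict[tuple[str, str], PhysiologyProfile] = {}
    for species, by_age in raw.items():
        if species == "ontogeny":
            continue
        for age_group, entry in by_age.items():
            bw = float(entry["body_weight_kg"])
            tissues = {
                name: TissueEntry(
                    volume_L=float(t["volume_fraction"]) * bw,
                    flow_fraction=(
                        float(t["flow_fraction"]) if "flow_fraction" in t else None
                    ),
                )
                for name, t in entry["tissues"].items()
            }
            profiles[(species, age_group)] = PhysiologyProfile(
                species=species,
                age_group=age_group,
                body_weight_kg=bw,
                cardiac_output_L_per_h=float(entry["cardiac_output_L_per_h"]),
                tissues=tissues,
            )
    ontogeny = OntogenyTable(factors=raw.get("ontogeny", {}))
    return {"profiles": profiles, "ontogeny": ontogeny}


def get_profile(
    species: str, age_group: str, config_path: str | Path | None = None
) -> PhysiologyProfile:
    """Return the validated physiology profile for a species/age group.

    Pure lookup of packaged defaults (or of a user override file); the
    same arguments always return identical values.
    """
    loaded = load_physiology(config_path)
    try:
        return loaded["profiles"][(species, age_group)]
    except KeyError:
        supported = sorted(loaded["profiles"])
        raise UnsupportedProfileError(
            f"unsupported combination ({species!r}, {age_group!r}); "
            f"supported: {supported}"
        ) from None


def default_ontogeny(config_path: str | Path | None = None) -> OntogenyTable:
    return load_physiology(config_path)["ontogeny"]


def ontogeny_factor(
    pathway_name: str, age_group: str, table: OntogenyTable | None = None
) -> float:
    """Scalar multiplier applied to the adult Vmax of one pathway.

    Raises :class:`MissingOntogenyError` if no entry exists — there is no
    silent default of 1.0.
    """
    if table is None:
        table = default_ontogeny()
    return table.factor(pathway_name, age_group)


def apply_ontogeny(
    pathways: Sequence, age_group: str, table: OntogenyTable | None = None
) -> list:
    """Scale adult-referenced pathway Vmax values to an age group.

    Each returned pathway has its ``vmax`` multiplied by the pathway's
    ontogeny factor; ``km`` is unchanged.  Applying the table twice
    scales twice — callers must start from adult-referenced values.
    """
    if table is None:
        table = default_ontogeny()
    return [
        dataclasses.replace(p, vmax=p.vmax * table.factor(p.name, age_group))
        for p in pathways
    ]
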
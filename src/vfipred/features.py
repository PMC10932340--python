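"""Feature engineering: from a missense variant to a named numeric vector.

Physico-chemical deltas (final minus initial residue), categorical transition
flags, positional context (domain/topology one-hots, first-position flag),
evolutionary conservation (per-column Shannon entropy of a homolog MSA),
the VFI tolerance score, AlphaFold per-residue confidence (pLDDT) and a
3-state secondary-structure one-hot.  Feature names are stable and ordered;
building the matrix is a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .variants import AA_ALPHABET, DataValidationError, DomainMap, ProteinVariant

# Kyte-Doolittle hydropathy index.
_HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Side-chain charge at pH 7; histidine treated as neutral.
_CHARGE = {aa: 0 for aa in AA_ALPHABET}
_CHARGE.update({"D": -1, "E": -1, "K": 1, "R": 1})

# Residue (monoisotopic-free average) masses in Da.
_MOLECULAR_WEIGHT = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16, "Q": 146.15,
    "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17, "L": 131.17, "K": 146.19,
    "M": 149.21, "F": 165.19, "P": 115.13, "S": 105.09, "T": 119.12, "W": 204.23,
    "Y": 181.19, "V": 117.15,
}

_POLAR = set("STCYNQDEKRH")
_AROMATIC = set("FWY")

# Theoretical maximum solvent accessibility (Tien et al. scale), normalized
# to [0, 1] by the tryptophan value.
_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0, "Q": 225.0,
    "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0, "L": 201.0, "K": 236.0,
    "M": 224.0, "F": 240.0, "P": 159.0, "S": 155.0, "T": 172.0, "W": 285.0,
    "Y": 263.0, "V": 174.0,
}
_ACCESSIBILITY = {aa: v / max(_MAX_ASA.values()) for aa, v in _MAX_ASA.items()}

DELTA_PROPERTIES = (
    "charge",
    "hydrophobicity",
    "mw",
    "polarity",
    "aromaticity",
    "accessibility",
)

TRANSITION_FLAGS = ("p_to_np", "np_to_p", "charge_gain", "charge_loss", "aromatic_change")

SECONDARY_STATES = ("H", "E", "C")


@dataclass(frozen=True)
class AminoAcidScales:
    """Per-residue property tables over the 20 standard residues."""

    charge: dict = field(default_factory=lambda: dict(_CHARGE))
    hydrophobicity: dict = field(default_factory=lambda: dict(_HYDROPHOBICITY))
    molecular_weight: dict = field(default_factory=lambda: dict(_MOLECULAR_WEIGHT))
    polarity: dict = field(
        default_factory=lambda: {aa: int(aa in _POLAR) for aa in AA_ALPHABET}
    )
    aromaticity: dict = field(
        default_factory=lambda: {aa: int(aa in _AROMATIC) for aa in AA_ALPHABET}
    )
    accessibility: dict = field(default_factory=lambda: dict(_ACCESSIBILITY))

    def __post_init__(self) -> None:
        for name in (
            "charge",
            "hydrophobicity",
            "molecular_weight",
            "polarity",
            "aromaticity",
            "accessibility",
        ):
            table = getattr(self, name)
            if set(table) != set(AA_ALPHABET):
                raise DataValidationError(
                    f"scale {name!r} must cover exactly the 20 standard residues"
                )

    @classmethod
    def from_yaml(cls, path) -> "AminoAcidScales":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = {
            "charge": self.charge,
            "hydrophobicity": self.hydrophobicity,
            "molecular_weight": self.molecular_weight,
            "polarity": self.polarity,
            "aromaticity": self.aromaticity,
            "accessibility": self.accessibility,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


def physchem_delta(variant: ProteinVariant, scales: AminoAcidScales | None = None) -> dict:
    """Property deltas (alt minus ref) and categorical transition flags.

    ``p_to_np`` fires when a polar residue becomes non-polar (and vice versa
    for ``np_to_p``); ``charge_gain``/``charge_loss`` track the magnitude of
    the side-chain charge; ``aromatic_change`` fires whenever aromaticity
    differs between the two residues.
    """
    s = scales or AminoAcidScales()
    ref, alt = variant.ref_aa, variant.alt_aa
    out = {
        "delta_charge": s.charge[alt] - s.charge[ref],
        "delta_hydrophobicity": s.hydrophobicity[alt] - s.hydrophobicity[ref],
        "delta_mw": s.molecular_weight[alt] - s.molecular_weight[ref],
        "delta_polarity": s.polarity[alt] - s.polarity[ref],
        "delta_aromaticity": s.aromaticity[alt] - s.aromaticity[ref],
        "delta_accessibility": s.accessibility[alt] - s.accessibility[ref],
        "p_to_np": int(s.polarity[ref] == 1 and s.polarity[alt] == 0),
        "np_to_p": int(s.polarity[ref] == 0 and s.polarity[alt] == 1),
        "charge_gain": int(abs(s.charge[alt]) > abs(s.charge[ref])),
        "charge_loss": int(abs(s.charge[alt]) < abs(s.charge[ref])),
        "aromatic_change": int(s.aromaticity[ref] != s.aromaticity[alt]),
    }
    return out


def first_position_flag(variant: ProteinVariant) -> int:
    """1 iff the substitution hits the initiator residue (position 1)."""
    return int(variant.position == 1)


def conservation_entropy(msa, position: int) -> float:
    """Shannon entropy (bits) of one alignment column, gaps excluded.

    0 for a fully conserved column, log2(20) for a uniform one.  An all-gap
    column is an error — it carries no conservation signal.
    """
    if position < 1 or position > msa.get_alignment_length():
        raise DataValidationError(f"alignment has no column {position}")
    column = [c for c in msa[:, position - 1].upper() if c not in "-."]
    if not column:
        raise DataValidationError(f"alignment column {position} contains only gaps")
    counts = pd.Series(column).value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_profile(msa) -> np.ndarray:
    return np.array(
        [conservation_entropy(msa, p) for p in range(1, msa.get_alignment_length() + 1)]
    )


@dataclass
class GeneProfiles:
    """Per-residue tracks the feature builder draws on."""

    vfi: np.ndarray
    plddt: np.ndarray
    entropy: np.ndarray
    secondary: str

    def __post_init__(self) -> None:
        lengths = {len(self.vfi), len(self.plddt), len(self.entropy), len(self.secondary)}
        if len(lengths) != 1:
            raise DataValidationError(f"profile tracks disagree in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.vfi)


def feature_names(
    domains: DomainMap, include_endpoint_aa: bool = True
) -> list[str]:
    """The canonical ordered feature-name list for a given domain map."""
    names = [f"delta_{p}" for p in DELTA_PROPERTIES]
    names += list(TRANSITION_FLAGS)
    names += ["first_position"]
    names += [f"topology_{t}" for t in ("extracellular", "transmembrane", "cytoplasmic")]
    names += [f"domain_{d}" for d in domains.domain_labels()]
    names += ["unknown_function", "calmodulin_interaction", "selectivity_filter"]
    names += ["conservation_entropy", "vfi", "plddt"]
    names += [f"secondary_{s}" for s in SECONDARY_STATES]
    if include_endpoint_aa:
        names += [f"initial_aa_{aa}" for aa in AA_ALPHABET]
        names += [f"final_aa_{aa}" for aa in AA_ALPHABET]
    return names


def assemble_features(
    variant: ProteinVariant,
    profiles: GeneProfiles,
    domains: DomainMap,
    scales: AminoAcidScales | None = None,
    include_endpoint_aa: bool = True,
) -> pd.Series:
    """Build the full named feature vector for one variant.

    Deterministic: identical inputs give bit-identical vectors.  With
    ``include_endpoint_aa=False`` the 40 initial/final residue one-hots are
    dropped (the severity task's anti-overfitting configuration).
    """
    pos = variant.position
    if pos > profiles.length:
        raise DataValidationError(
            f"variant {variant} outside profile range 1..{profiles.length}"
        )
    values: dict[str, float] = {}
    values.update(physchem_delta(variant, scales))
    values["first_position"] = first_position_flag(variant)
    topo = domains.topology_at(pos)
    for t in ("extracellular", "transmembrane", "cytoplasmic"):
        values[f"topology_{t}"] = int(topo == t)
    dom_label, flags = domains.domain_at(pos)
    for d in domains.domain_labels():
        values[f"domain_{d}"] = int(dom_label == d)
    for fl in ("unknown_function", "calmodulin_interaction", "selectivity_filter"):
        values[fl] = int(fl in flags)
    values["conservation_entropy"] = float(profiles.entropy[pos - 1])
    values["vfi"] = float(profiles.vfi[pos - 1])
    values["plddt"] = float(profiles.plddt[pos - 1])
    ss = profiles.secondary[pos - 1]
    for s in SECONDARY_STATES:
        values[f"secondary_{s}"] = int(ss == s)
    if include_endpoint_aa:
        for aa in AA_ALPHABET:
            values[f"initial_aa_{aa}"] = int(variant.ref_aa == aa)
            values[f"final_aa_{aa}"] = int(variant.alt_aa == aa)
    names = feature_names(domains, include_endpoint_aa)
    return pd.Series([values[n] for n in names], index=names, dtype=float, name=str(variant))


def build_feature_matrix(
    variants: list[ProteinVariant],
    profiles: GeneProfiles,
    domains: DomainMap,
    scales: AminoAcidScales | None = None,
    include_endpoint_aa: bool = True,
) -> pd.DataFrame:
    """Feature matrix (variants x features) with stable column order."""
    rows = [
        assemble_features(v, profiles, domains, scales, include_endpoint_aa)
        for v in variants
    ]
    return pd.DataFrame(rows)
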
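"""Parsing and validation of variant-level inputs.

Everything enters the pipeline at the protein level: a missense variant is a
single amino-acid substitution named in the conventional short form
("G256E", or HGVS-style "p.Gly256Glu").  Protein positions are 1-based
inclusive throughout the package; no 0-based interface is exposed.

Nucleotide-level information enters only through :class:`CodingSequence`,
which supports exhaustive enumeration of the single-base substitution
landscape of a transcript (how many substitutions are synonymous, missense
or stop-introducing, and how many distinct protein-level missense variants
they reach).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from Bio.PDB import PDBParser

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = dict(protein_letters_1to3)

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")


class VariantParseError(ValueError):
    """Raised when a variant string cannot be interpreted as a missense change."""


class DataValidationError(ValueError):
    """Raised when an input table or profile violates its contract."""


@dataclass(frozen=True, order=True)
class ProteinVariant:
    """A single amino-acid substitution: reference residue, 1-based position, alternate residue."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AA_ALPHABET:
            raise VariantParseError(f"unknown reference residue {self.ref_aa!r}")
        if self.alt_aa not in AA_ALPHABET:
            raise VariantParseError(f"unknown alternate residue {self.alt_aa!r}")
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise VariantParseError(
                f"synonymous change {self.ref_aa}{self.position}{self.alt_aa} is not a missense variant"
            )

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def long_form(self) -> str:
        return f"p.{_ONE_TO_THREE[self.ref_aa]}{self.position}{_ONE_TO_THREE[self.alt_aa]}"


def _normalize_residue(token: str) -> str:
    if len(token) == 1:
        code = token.upper()
    else:
        code = _THREE_TO_ONE.get(token.upper())
        if code is None:
            raise VariantParseError(f"unknown residue code {token!r}")
    if code not in AA_ALPHABET:
        raise VariantParseError(f"residue {token!r} is outside the 20-letter alphabet")
    return code


def parse_variant(text: str) -> ProteinVariant:
    """Parse ``"G256E"`` or ``"p.Gly256Glu"`` into a :class:`ProteinVariant`.

    Three-letter codes and the HGVS ``p.`` prefix are accepted and normalised
    to one-letter form.  Synonymous changes, stop codons, positions below 1
    and non-standard residues are rejected with a :class:`VariantParseError`
    naming the offending token.
    """
    if not text or not text.strip():
        raise VariantParseError("empty variant string")
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"cannot parse variant string {text!r}")
    ref_tok, pos_tok, alt_tok = m.groups()
    if len(ref_tok) == 2 or len(alt_tok) == 2:
        raise VariantParseError(f"ambiguous residue code in {text!r}")
    position = int(pos_tok)
    if position == 0:
        raise VariantParseError(f"position 0 in {text!r}; positions are 1-based")
    ref = _normalize_residue(ref_tok)
    alt = _normalize_residue(alt_tok)
    if ref == alt:
        raise VariantParseError(f"{text!r} is synonymous (ref == alt)")
    return ProteinVariant(ref, position, alt)


# ---------------------------------------------------------------------------
# Coding sequences and the single-base substitution landscape
# ---------------------------------------------------------------------------

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_BASES = "ACGT"


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence (A/C/G/T, length divisible by 3)."""

    nucleotides: str

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", seq)
        if len(seq) % 3 != 0:
            raise DataValidationError(
                f"coding sequence length {len(seq)} is not divisible by 3"
            )
        bad = set(seq) - set(_BASES)
        if bad:
            raise DataValidationError(f"non-ACGT characters in coding sequence: {sorted(bad)}")
        internal_stops = [
            i // 3 + 1
            for i in range(0, max(len(seq) - 3, 0), 3)
            if _CODON_TO_AA[seq[i : i + 3]] == "*"
        ]
        if internal_stops:
            warnings.warn(
                f"internal stop codon(s) at codon position(s) {internal_stops}",
                stacklevel=2,
            )

    @property
    def codon_count(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def protein(self) -> str:
        """Translated protein, excluding a trailing stop codon if present."""
        aas = [_CODON_TO_AA[c] for c in self.codons()]
        if aas and aas[-1] == "*":
            aas = aas[:-1]
        return "".join(aas)


@dataclass(frozen=True)
class MissenseSummary:
    nonsyn_substitutions: int
    stop_introducing: int
    distinct_missense_variants: int
    synonymous: int

    @property
    def total_substitutions(self) -> int:
        return self.nonsyn_substitutions + self.synonymous


def enumerate_missense(cds: CodingSequence) -> MissenseSummary:
    """Classify every one of the 9 x codon_count single-base substitutions.

    Each substitution is synonymous (same residue, including stop-to-stop) or
    non-synonymous; non-synonymous substitutions that create a stop codon are
    additionally counted as stop-introducing.  ``distinct_missense_variants``
    counts unique (position, alternate residue) pairs among substitutions
    where both the reference and alternate residues are standard amino acids.
    """
    nonsyn = 0
    stops = 0
    syn = 0
    distinct: set[tuple[int, str]] = set()
    for idx, codon in enumerate(cds.codons()):
        ref_aa = _CODON_TO_AA[codon]
        for offset in range(3):
            for base in _BASES:
                if base == codon[offset]:
                    continue
                alt_codon = codon[:offset] + base + codon[offset + 1 :]
                alt_aa = _CODON_TO_AA[alt_codon]
                if alt_aa == ref_aa:
                    syn += 1
                else:
                    nonsyn += 1
                    if alt_aa == "*":
                        stops += 1
                    elif ref_aa != "*":
                        distinct.add((idx + 1, alt_aa))
    return MissenseSummary(nonsyn, stops, len(distinct), syn)


def missense_possible_per_position(cds: CodingSequence) -> list[int]:
    """Distinct missense residues reachable by a single base change, per codon."""
    counts = []
    for codon in cds.codons():
        ref_aa = _CODON_TO_AA[codon]
        reachable: set[str] = set()
        if ref_aa != "*":
            for offset in range(3):
                for base in _BASES:
                    if base == codon[offset]:
                        continue
                    alt_aa = _CODON_TO_AA[codon[:offset] + base + codon[offset + 1 :]]
                    if alt_aa not in ("*", ref_aa):
                        reachable.add(alt_aa)
        counts.append(len(reachable))
    return counts


# ---------------------------------------------------------------------------
# Allele tables
# ---------------------------------------------------------------------------


@dataclass
class AlleleTable:
    """Per-variant allele observations, possibly from several population panels.

    Wraps a DataFrame with columns ``variant`` (:class:`ProteinVariant`),
    ``allele_count``, ``total_alleles`` and ``source``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"variant", "allele_count", "total_alleles", "source"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataValidationError(f"allele table missing columns: {sorted(missing)}")
        f = self.frame
        if (f["allele_count"] < 0).any():
            raise DataValidationError("negative allele_count")
        if (f["total_alleles"] <= 0).any():
            raise DataValidationError("total_alleles must be positive")
        if (f["allele_count"] > f["total_alleles"]).any():
            raise DataValidationError("allele_count exceeds total_alleles")
        dup = f.duplicated(subset=["variant", "source"])
        if dup.any():
            dupes = f.loc[dup, "variant"].astype(str).tolist()
            raise DataValidationError(f"duplicate (variant, source) rows: {dupes}")

    def __len__(self) -> int:
        return len(self.frame)

    def validate_against(self, protein: str) -> None:
        """Check every variant's position and reference residue against a protein sequence."""
        for v in self.frame["variant"]:
            if v.position > len(protein):
                raise DataValidationError(
                    f"variant {v} beyond protein length {len(protein)}"
                )
            if protein[v.position - 1] != v.ref_aa:
                raise DataValidationError(
                    f"variant {v}: sequence has {protein[v.position - 1]} at {v.position}"
                )


def read_allele_table(path, sources: list[str] | None = None) -> AlleleTable:
    """Read a TSV with columns variant, allele_count, total_alleles, source."""
    raw = pd.read_csv(path, sep="\t", dtype={"source": str})
    rows = []
    for i, row in raw.iterrows():
        try:
            variant = parse_variant(str(row["variant"]))
            ac = int(row["allele_count"])
            an = int(row["total_alleles"])
        except (VariantParseError, KeyError, ValueError) as exc:
            raise DataValidationError(f"{path}, data row {i + 1}: {exc}") from exc
        rows.append(
            {
                "variant": variant,
                "allele_count": ac,
                "total_alleles": an,
                "source": str(row["source"]),
            }
        )
    frame = pd.DataFrame(rows, columns=["variant", "allele_count", "total_alleles", "source"])
    if sources is not None:
        unknown = set(frame["source"]) - set(sources)
        if unknown:
            raise DataValidationError(f"unexpected sources {sorted(unknown)}; allowed {sources}")
    return AlleleTable(frame)


# ---------------------------------------------------------------------------
# Domain / topology maps
# ---------------------------------------------------------------------------

TOPOLOGY_LABELS = ("extracellular", "transmembrane", "cytoplasmic")
KNOWN_FLAGS = ("unknown_function", "calmodulin_interaction", "selectivity_filter")


@dataclass
class DomainMap:
    """Interval annotations of the protein: a topology track covering 1..L
    plus optional functional domains (at most one per residue)."""

    topology: pd.DataFrame  # start, end, label
    domains: pd.DataFrame  # start, end, label, flags (frozenset)
    length: int

    def __post_init__(self) -> None:
        covered = [False] * self.length
        for _, row in self.topology.iterrows():
            if row["label"] not in TOPOLOGY_LABELS:
                raise DataValidationError(f"unknown topology label {row['label']!r}")
            for p in range(row["start"], row["end"] + 1):
                if p < 1 or p > self.length:
                    raise DataValidationError(f"topology interval out of range at {p}")
                if covered[p - 1]:
                    raise DataValidationError(f"topology intervals overlap at residue {p}")
                covered[p - 1] = True
        holes = [i + 1 for i, c in enumerate(covered) if not c]
        if holes:
            raise DataValidationError(f"topology track leaves residues uncovered: {holes[:5]}...")
        seen = [0] * self.length
        for _, row in self.domains.iterrows():
            for p in range(row["start"], row["end"] + 1):
                seen[p - 1] += 1
                if seen[p - 1] > 1:
                    raise DataValidationError(f"functional domains overlap at residue {p}")

    def topology_at(self, position: int) -> str:
        for _, row in self.topology.iterrows():
            if row["start"] <= position <= row["end"]:
                return row["label"]
        raise DataValidationError(f"position {position} outside topology track")

    def domain_at(self, position: int) -> tuple[str | None, frozenset]:
        for _, row in self.domains.iterrows():
            if row["start"] <= position <= row["end"]:
                return row["label"], row["flags"]
        return None, frozenset()

    def domain_labels(self) -> list[str]:
        return sorted(self.domains["label"].unique())


def read_domain_map(path, length: int) -> DomainMap:
    """Read a domain TSV (start, end, label, track, flags) into a DomainMap.

    ``track`` is ``topology`` or ``domain``; ``flags`` is a comma-separated
    list (empty allowed) drawn from the known functional flags.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    topo_rows, dom_rows = [], []
    for i, row in raw.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise DataValidationError(f"{path}, data row {i + 1}: {exc}") from exc
        if end < start:
            raise DataValidationError(f"{path}, data row {i + 1}: end < start")
        flags = frozenset(
            f for f in str(row.get("flags", "") or "").split(",") if f and f != "nan"
        )
        unknown = flags - set(KNOWN_FLAGS)
        if unknown:
            raise DataValidationError(f"unknown flags {sorted(unknown)} in row {i + 1}")
        rec = {"start": start, "end": end, "label": row["label"], "flags": flags}
        if row["track"] == "topology":
            topo_rows.append(rec)
        elif row["track"] == "domain":
            dom_rows.append(rec)
        else:
            raise DataValidationError(f"unknown track {row['track']!r} in row {i + 1}")
    return DomainMap(
        topology=pd.DataFrame(topo_rows, columns=["start", "end", "label", "flags"]),
        domains=pd.DataFrame(dom_rows, columns=["start", "end", "label", "flags"]),
        length=length,
    )


# ---------------------------------------------------------------------------
# pLDDT profiles
# ---------------------------------------------------------------------------


@dataclass
class PlddtProfile:
    """Per-residue model-confidence values in [0, 100]."""

    values: list[float]

    def __post_init__(self) -> None:
        bad = [v for v in self.values if not (0.0 <= v <= 100.0)]
        if bad:
            raise DataValidationError(f"pLDDT values outside [0, 100]: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def at(self, position: int) -> float:
        if not 1 <= position <= len(self.values):
            raise DataValidationError(f"position {position} outside pLDDT profile")
        return self.values[position - 1]


def read_plddt(path, mode: str = "pdb_bfactor", chain: str | None = None) -> PlddtProfile:
    """Read per-residue confidence from a PDB B-factor column or a JSON list.

    In ``pdb_bfactor`` mode the CA atom's B-factor is taken as the residue
    value (per-residue confidence is constant across atoms in predicted
    models, and disordered-atom handling keeps the highest-occupancy
    location).  Residue numbering must be contiguous from 1; gaps are an
    error naming the missing positions.
    """
    if mode == "json":
        with open(path) as fh:
            payload = json.load(fh)
        values = payload["plddt"] if isinstance(payload, dict) else payload
        return PlddtProfile([float(v) for v in values])
    if mode != "pdb_bfactor":
        raise ValueError(f"unknown pLDDT mode {mode!r}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", path)
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain is None:
        if len(chains) != 1:
            raise DataValidationError(
                f"{len(chains)} chains present; specify which to read"
            )
        target = chains[0]
    else:
        matches = [c for c in chains if c.id == chain]
        if not matches:
            raise DataValidationError(f"chain {chain!r} not found")
        target = matches[0]
    by_resseq: dict[int, float] = {}
    for residue in target:
        if "CA" not in residue:
            continue
        by_resseq[residue.id[1]] = float(residue["CA"].get_bfactor())
    if not by_resseq:
        raise DataValidationError("no CA atoms found")
    length = max(by_resseq)
    gaps = [p for p in range(1, length + 1) if p not in by_resseq]
    if gaps:
        raise DataValidationError(f"missing residues in model: {gaps}")
    return PlddtProfile([by_resseq[p] for p in range(1, length + 1)])


# ---------------------------------------------------------------------------
# Sequences, alignments, labeled datasets, secondary structure
# ---------------------------------------------------------------------------


def read_fasta_sequence(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataValidationError(f"no sequences in {path}")
    return str(records[0].seq).upper()


def read_msa(path):
    """Read a FASTA multiple sequence alignment (Bio.Align object)."""
    return AlignIO.read(str(path), "fasta")


def read_secondary_structure(path, length: int | None = None) -> str:
    """Read a per-residue 3-state (H/E/C) annotation stored as a single line."""
    with open(path) as fh:
        track = "".join(line.strip() for line in fh if not line.startswith(">"))
    bad = set(track) - set("HEC")
    if bad:
        raise DataValidationError(f"unknown secondary-structure symbols {sorted(bad)}")
    if length is not None and len(track) != length:
        raise DataValidationError(
            f"secondary-structure track length {len(track)} != protein length {length}"
        )
    return track


PATHOGENICITY_LABELS = {"tolerated": 0, "pathogenic": 1}
SEVERITY_LABELS = ("benign", "benign/severe", "severe")
SPLITS = ("train", "test", "unassigned")


def read_labeled_dataset(path, task: str = "pathogenicity") -> pd.DataFrame:
    """Read a labeled-variant CSV (variant, label, split) and binarize labels.

    Pathogenicity labels map tolerated -> 0, pathogenic -> 1.  Severity rows
    keep their raw three-state label; binarization is the severity
    pipeline's responsibility.
    """
    raw = pd.read_csv(path, dtype=str)
    for col in ("variant", "label", "split"):
        if col not in raw.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    variants = [parse_variant(v) for v in raw["variant"]]
    bad_split = set(raw["split"]) - set(SPLITS)
    if bad_split:
        raise DataValidationError(f"unknown split values {sorted(bad_split)}")
    out = pd.DataFrame({"variant": variants, "split": raw["split"]})
    if task == "pathogenicity":
        unknown = set(raw["label"]) - set(PATHOGENICITY_LABELS)
        if unknown:
            raise DataValidationError(f"unknown labels {sorted(unknown)}")
        out["label"] = [PATHOGENICITY_LABELS[l] for l in raw["label"]]
    elif task == "severity":
        unknown = set(raw["label"]) - set(SEVERITY_LABELS)
        if unknown:
            raise DataValidationError(f"unknown severity labels {sorted(unknown)}")
        out["label"] = raw["label"].tolist()
    else:
        raise ValueError(f"unknown task {task!r}")
    return out
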
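"""Synthetic gene generator: every input the pipeline consumes, with
controllable signal strength and full determinism under a master seed.

The generator emulates the statistical structure of a curated ion-channel
variant study, not the biology of any real gene: a membrane-protein-like
domain layout (cytoplasmic termini, transmembrane segments, a pore with a
selectivity filter, calmodulin-interaction helices, a region of unknown
function) defines a designed per-position tolerance landscape ``t(p)`` in
[0, 1].  All tracks derive from it:

* allele counts are Poisson draws whose rates are proportional to ``t(p)``,
  split over two population panels with different denominators;
* pLDDT is an affine transform of the smoothed landscape plus noise
  (positively correlated with the VFI profile by construction);
* MSA column conservation is anti-correlated with tolerance, so Shannon
  entropy rises where variation is tolerated;
* pathogenicity labels follow a logistic function of intolerance plus
  domain flags; severity labels are driven by domain context only, so the
  identity of the substituted residues carries no severity signal.

Class counts and split sizes mirror a curated-dataset design: 285 tolerated
and 269 pathogenic variants, a training split of 206 pathogenic + 10
tolerated plus 208 extra primate-derived tolerated variants (the batch that
carries the label noise, emulating heuristic labeling), and a held-out test
split of 27 tolerated + 62 pathogenic.  The severity subset holds 62
benign, 32 benign/severe and 180 severe variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import vfi as vfi_mod
from .features import GeneProfiles, entropy_profile
from .variants import (
    AA_ALPHABET,
    AlleleTable,
    CodingSequence,
    DomainMap,
    PlddtProfile,
    ProteinVariant,
    missense_possible_per_position,
)
from .variants import _CODON_TO_AA  # standard-code codon table

_SENSE_CODONS = sorted(c for c, aa in _CODON_TO_AA.items() if aa != "*")

# (start, end, domain label or None, topology, flags, base tolerance)
_REGION_LAYOUT = [
    (1, 90, None, "cytoplasmic", (), 0.80),
    (91, 110, "s1", "transmembrane", (), 0.25),
    (111, 130, None, "extracellular", (), 0.60),
    (131, 150, "s2", "transmembrane", (), 0.25),
    (151, 170, None, "cytoplasmic", (), 0.60),
    (171, 190, "s3", "transmembrane", (), 0.25),
    (191, 210, None, "extracellular", (), 0.55),
    (211, 230, "voltage_sensor", "transmembrane", (), 0.10),
    (231, 250, None, "cytoplasmic", (), 0.50),
    (251, 270, "s5", "transmembrane", (), 0.20),
    (271, 285, None, "extracellular", (), 0.40),
    (286, 300, "pore", "transmembrane", ("selectivity_filter",), 0.05),
    (301, 320, "s6", "transmembrane", (), 0.20),
    (321, 360, "helix_a", "cytoplasmic", ("calmodulin_interaction",), 0.15),
    (361, 420, "helix_b", "cytoplasmic", ("calmodulin_interaction",), 0.20),
    (421, 530, None, "cytoplasmic", (), 0.85),
    (531, 600, "helix_c", "cytoplasmic", (), 0.35),
    (601, 700, "unknown_region", "cytoplasmic", ("unknown_function",), 0.50),
    (701, 872, None, "cytoplasmic", (), 0.90),
]


@dataclass(frozen=True)
class GenePreset:
    """Frozen generation conditions for one synthetic gene study."""

    name: str = "default"
    length: int = 872
    alpha_true: float | None = None  # None -> median of non-zero f
    sigma_true: float = 2.0
    noise_rate: float = 0.05  # label-noise rate on the primate-like batch
    effect_size: float = 60.0  # steepness of the pathogenicity logistic
    panel_sizes: tuple = (("v2", 150_000), ("v3", 280_000))
    variant_rate: float = 16.0  # Poisson mean allele count per position at full tolerance
    msa_depth: int = 48
    plddt_noise_sd: float = 7.0
    secondary_error_rate: float = 0.2  # per-residue 3-state annotation noise
    n_tolerated: int = 285
    n_pathogenic: int = 269
    train_pathogenic: int = 206
    train_tolerated: int = 10
    test_pathogenic: int = 62
    test_tolerated: int = 27
    primate_batch: int = 208
    severity_counts: tuple = (("benign", 62), ("benign/severe", 32), ("severe", 180))
    master_seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if self.length != _REGION_LAYOUT[-1][1]:
            raise ValueError(
                f"region layout covers 1..{_REGION_LAYOUT[-1][1]}, preset length is {self.length}"
            )


@dataclass
class SyntheticGene:
    """All generated per-gene inputs plus the hidden truth used to make them."""

    preset: GenePreset
    cds: CodingSequence
    protein: str
    allele_table: AlleleTable
    msa_rows: list[tuple[str, str]]  # (name, aligned sequence)
    plddt: PlddtProfile
    domain_map: DomainMap
    secondary: str
    true_tolerance: np.ndarray
    smoothed_tolerance: np.ndarray

    class _Msa:
        """Minimal alignment view (length + column access) over the stored rows."""

        def __init__(self, rows):
            self._rows = rows

        def get_alignment_length(self):
            return len(self._rows[0][1])

        def __getitem__(self, key):
            rows, col = key
            if rows != slice(None):
                raise IndexError("only full-column access is supported")
            return "".join(seq[col] for _, seq in self._rows)

    @property
    def msa(self):
        return SyntheticGene._Msa(self.msa_rows)

    def position_profile(
        self, sigma: float | None = None, alpha: float | None = None
    ) -> pd.DataFrame:
        merged = vfi_mod.merge_frequency_sources(self.allele_table)
        return vfi_mod.build_position_profile(
            merged,
            self.cds,
            sigma=self.preset.sigma_true if sigma is None else sigma,
            alpha=self.preset.alpha_true if alpha is None else alpha,
        )

    def profiles(self, sigma: float | None = None) -> GeneProfiles:
        table = self.position_profile(sigma=sigma)
        return GeneProfiles(
            vfi=table["vfi"].to_numpy(),
            plddt=np.asarray(self.plddt.values),
            entropy=entropy_profile(self.msa),
            secondary=self.secondary,
        )


def _region_of(position: int):
    for start, end, label, topo, flags, tol in _REGION_LAYOUT:
        if start <= position <= end:
            return start, end, label, topo, flags, tol
    raise ValueError(f"position {position} outside layout")


def _build_domain_map(length: int) -> DomainMap:
    topo_rows = [
        {"start": s, "end": e, "label": topo, "flags": frozenset()}
        for s, e, _, topo, _, _ in _REGION_LAYOUT
    ]
    dom_rows = [
        {"start": s, "end": e, "label": lab, "flags": frozenset(flags)}
        for s, e, lab, _, flags, _ in _REGION_LAYOUT
        if lab is not None
    ]
    return DomainMap(
        topology=pd.DataFrame(topo_rows),
        domains=pd.DataFrame(dom_rows),
        length=length,
    )


def _true_tolerance(preset: GenePreset, rng: np.random.Generator) -> np.ndarray:
    base = np.empty(preset.length)
    for s, e, _, _, _, tol in _REGION_LAYOUT:
        base[s - 1 : e] = tol
    wiggle = rng.normal(0.0, 1.0, preset.length)
    kernel = vfi_mod.gaussian_kernel(6.0, 24)
    smooth_wiggle = np.convolve(wiggle, kernel, mode="same")
    return np.clip(base + 0.08 * smooth_wiggle, 0.02, 0.98)


def make_gene(preset: GenePreset | None = None) -> SyntheticGene:
    """Generate the full input bundle for one synthetic gene."""
    preset = preset or GenePreset()
    seeds = np.random.SeedSequence(preset.master_seed).spawn(6)
    rng_cds, rng_tol, rng_allele, rng_msa, rng_plddt, rng_ss = (
        np.random.default_rng(s) for s in seeds
    )

    codons = [_SENSE_CODONS[i] for i in rng_cds.integers(len(_SENSE_CODONS), size=preset.length)]
    cds = CodingSequence("".join(codons))
    protein = cds.protein()
    tol = _true_tolerance(preset, rng_tol)

    # Allele observations: Poisson counts per possible missense variant,
    # rate proportional to the position's tolerance, scaled per panel.
    possible = missense_possible_per_position(cds)
    rows = []
    for source, panel_n in preset.panel_sizes:
        rate_scale = preset.variant_rate * panel_n / max(n for _, n in preset.panel_sizes)
        for p in range(1, preset.length + 1):
            alts = _reachable_alts(codons[p - 1])
            for alt in sorted(alts):
                count = rng_allele.poisson(rate_scale * tol[p - 1] / max(len(alts), 1))
                if count > 0:
                    rows.append(
                        {
                            "variant": ProteinVariant(protein[p - 1], p, alt),
                            "allele_count": int(count),
                            "total_alleles": panel_n,
                            "source": source,
                        }
                    )
    allele_table = AlleleTable(
        pd.DataFrame(rows, columns=["variant", "allele_count", "total_alleles", "source"])
    )

    # MSA: column conservation anti-correlated with tolerance, with
    # per-column jitter so conservation is a noisy correlate of the
    # landscape rather than a clean readout of it.
    conservation = np.clip(
        1.0 - 0.6 * tol + rng_msa.normal(0.0, 0.15, preset.length), 0.05, 0.98
    )
    alphabet = np.array(list(AA_ALPHABET))
    msa_rows = [("query", protein)]
    for s in range(1, preset.msa_depth):
        keep = rng_msa.random(preset.length) < conservation
        random_res = alphabet[rng_msa.integers(20, size=preset.length)]
        seq = np.where(keep, np.array(list(protein)), random_res)
        gaps = rng_msa.random(preset.length) < 0.02
        seq = np.where(gaps, "-", seq)
        msa_rows.append((f"homolog_{s}", "".join(seq)))

    # pLDDT: affine transform of the smoothed landscape plus noise.
    kernel = vfi_mod.gaussian_kernel(4.0, 16)
    smooth_tol = np.convolve(tol, kernel, mode="same")
    plddt_vals = np.clip(
        35.0 + 50.0 * smooth_tol + rng_plddt.normal(0.0, preset.plddt_noise_sd, preset.length),
        0.0,
        100.0,
    )
    plddt = PlddtProfile(list(plddt_vals))

    # 3-state annotation with per-residue errors, as a predicted (not
    # observed) secondary structure would have.
    states = np.array(list("HEC"))
    secondary_arr = np.array([_secondary_state(p) for p in range(1, preset.length + 1)])
    flip = rng_ss.random(preset.length) < preset.secondary_error_rate
    wrong = np.array(
        [states[states != s0][rng_ss.integers(2)] for s0 in secondary_arr]
    )
    secondary = "".join(np.where(flip, wrong, secondary_arr))
    label_kernel = vfi_mod.gaussian_kernel(
        preset.sigma_true, vfi_mod.default_radius(preset.sigma_true)
    )
    return SyntheticGene(
        preset=preset,
        cds=cds,
        protein=protein,
        allele_table=allele_table,
        msa_rows=msa_rows,
        plddt=plddt,
        domain_map=_build_domain_map(preset.length),
        secondary=secondary,
        true_tolerance=tol,
        smoothed_tolerance=np.convolve(tol, label_kernel, mode="same"),
    )


def _reachable_alts(codon: str) -> set[str]:
    ref = _CODON_TO_AA[codon]
    alts = set()
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            aa = _CODON_TO_AA[codon[:i] + b + codon[i + 1 :]]
            if aa not in ("*", ref):
                alts.add(aa)
    return alts


def _secondary_state(position: int) -> str:
    _, _, label, topo, flags, _ = _region_of(position)
    if "selectivity_filter" in flags:
        return "E"
    if topo == "transmembrane" or (label or "").startswith("helix"):
        return "H"
    return "C"


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _candidate_pool(gene: SyntheticGene) -> pd.DataFrame:
    """All distinct single-base-reachable missense variants with their
    pathogenicity propensity under the hidden model."""
    preset = gene.preset
    codons = gene.cds.codons()
    records = []
    for p in range(1, preset.length + 1):
        _, _, _, topo, flags, _ = _region_of(p)
        # Labels follow the locally smoothed landscape — regional tolerance,
        # the quantity the VFI profile estimates — plus domain-flag bonuses.
        eta = preset.effect_size * (0.45 - gene.smoothed_tolerance[p - 1])
        eta += 1.2 * ("selectivity_filter" in flags)
        eta += 0.8 * ("calmodulin_interaction" in flags)
        eta += 0.5 * (topo == "transmembrane")
        for alt in sorted(_reachable_alts(codons[p - 1])):
            records.append(
                {
                    "variant": ProteinVariant(gene.protein[p - 1], p, alt),
                    "position": p,
                    "p_path": _sigmoid(eta),
                }
            )
    return pd.DataFrame(records)


def _weighted_take(
    pool: pd.DataFrame, weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    w = np.clip(np.asarray(weights, dtype=float), 1e-12, None)
    idx = rng.choice(len(pool), size=k, replace=False, p=w / w.sum())
    return pool.index.to_numpy()[idx]


def make_labels(gene: SyntheticGene, task: str = "pathogenicity") -> pd.DataFrame:
    """Labeled variant dataset with train/test/unassigned split.

    Pathogenicity: exact 285/269 class counts drawn by propensity-weighted
    sampling from the reachable-missense pool, plus the primate-like extra
    tolerated training batch carrying ``noise_rate`` mislabeled rows.
    Severity: exact 62/32/180 three-state counts, driven by domain flags
    only, split ~80/20 per class.
    """
    preset = gene.preset
    seeds = np.random.SeedSequence(preset.master_seed + 1).spawn(2)
    rng = np.random.default_rng(seeds[0] if task == "pathogenicity" else seeds[1])
    pool = _candidate_pool(gene)

    if task == "pathogenicity":
        path_idx = _weighted_take(pool, pool["p_path"].to_numpy(), preset.n_pathogenic, rng)
        rest = pool.drop(index=path_idx)
        tol_idx = _weighted_take(rest, 1.0 - rest["p_path"].to_numpy(), preset.n_tolerated, rng)
        rows = []
        for name, idx, n_train, n_test in (
            ("pathogenic", path_idx, preset.train_pathogenic, preset.test_pathogenic),
            ("tolerated", tol_idx, preset.train_tolerated, preset.test_tolerated),
        ):
            order = rng.permutation(len(idx))
            for rank, i in enumerate(order):
                split = (
                    "train"
                    if rank < n_train
                    else "test" if rank < n_train + n_test else "unassigned"
                )
                rows.append(
                    {"variant": pool.loc[idx[i], "variant"], "label": name, "split": split}
                )
        # primate-like batch: extra tolerated training rows, a noise_rate
        # fraction of which are drawn from the pathogenic-propensity pool
        # (heuristically labeled, hence mislabeled).
        remaining = pool.drop(index=np.concatenate([path_idx, tol_idx]))
        n_noisy = int(round(preset.noise_rate * preset.primate_batch))
        clean_idx = _weighted_take(
            remaining, 1.0 - remaining["p_path"].to_numpy(), preset.primate_batch - n_noisy, rng
        )
        remaining2 = remaining.drop(index=clean_idx)
        noisy_idx = _weighted_take(remaining2, remaining2["p_path"].to_numpy(), n_noisy, rng)
        for i in np.concatenate([clean_idx, noisy_idx]):
            rows.append({"variant": pool.loc[i, "variant"], "label": "tolerated", "split": "train"})
        out = pd.DataFrame(rows)
    elif task == "severity":
        # Severity propensity uses positional context only — never the
        # residue identities — so endpoint one-hots carry no signal.
        eta = np.zeros(len(pool))
        for j, p in enumerate(pool["position"]):
            _, _, _, topo, flags, _ = _region_of(int(p))
            eta[j] = (
                2.2 * ("selectivity_filter" in flags)
                + 1.6 * ("calmodulin_interaction" in flags)
                + 0.9 * (topo == "transmembrane")
                + 0.5 * ("unknown_function" in flags)
                - 1.0
            )
        p_sev = _sigmoid(2.0 * eta)
        # restrict to pathogenic-like candidates
        path_like = pool[pool["p_path"] > 0.5]
        p_sev = p_sev[pool["p_path"].to_numpy() > 0.5]
        rows = []
        taken: list[int] = []
        for label, count in preset.severity_counts:
            avail = path_like.drop(index=taken)
            w = pd.Series(p_sev, index=path_like.index).drop(index=taken).to_numpy()
            weights = w if label in ("severe", "benign/severe") else 1.0 - w
            idx = _weighted_take(avail, weights, count, rng)
            taken.extend(idx)
            n_train = int(round(0.8 * count))
            order = rng.permutation(len(idx))
            for rank, i in enumerate(order):
                rows.append(
                    {
                        "variant": path_like.loc[idx[i], "variant"],
                        "label": label,
                        "split": "train" if rank < n_train else "test",
                    }
                )
        out = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown task {task!r}")
    out["variant_str"] = out["variant"].astype(str)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fixture writers (text formats only)
# ---------------------------------------------------------------------------


def write_fixtures(gene: SyntheticGene, out_dir) -> dict:
    """Write every input file the readers consume; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, text):
        path = out / name
        path.write_text(text)
        paths[name] = path
        return path

    _write("cds.fasta", f">synthetic_cds\n{gene.cds.nucleotides}\n")
    _write("protein.fasta", f">synthetic_protein\n{gene.protein}\n")

    lines = ["variant\tallele_count\ttotal_alleles\tsource"]
    for _, row in gene.allele_table.frame.iterrows():
        lines.append(
            f"{row['variant']}\t{row['allele_count']}\t{row['total_alleles']}\t{row['source']}"
        )
    _write("alleles.tsv", "\n".join(lines) + "\n")

    _write("msa.fasta", "".join(f">{n}\n{s}\n" for n, s in gene.msa_rows))

    # CA-only PDB with pLDDT in the B-factor column.
    pdb_lines = []
    for i, v in enumerate(gene.plddt.values, start=1):
        pdb_lines.append(
            f"ATOM  {i:>5}  CA  ALA A{i:>4}    {0.0:8.3f}{0.0:8.3f}{float(i):8.3f}"
            f"{1.00:6.2f}{v:6.2f}           C"
        )
    _write("plddt.pdb", "\n".join(pdb_lines) + "\nEND\n")
    _write("plddt.json", json.dumps({"plddt": [float(v) for v in gene.plddt.values]}))

    dm_lines = ["start\tend\tlabel\ttrack\tflags"]
    for _, row in gene.domain_map.topology.iterrows():
        dm_lines.append(f"{row['start']}\t{row['end']}\t{row['label']}\ttopology\t")
    for _, row in gene.domain_map.domains.iterrows():
        dm_lines.append(
            f"{row['start']}\t{row['end']}\t{row['label']}\tdomain\t{','.join(sorted(row['flags']))}"
        )
    _write("domains.tsv", "\n".join(dm_lines) + "\n")

    _write("secondary.txt", gene.secondary + "\n")

    for task in ("pathogenicity", "severity"):
        labels = make_labels(gene, task)
        csv = labels[["variant_str", "label", "split"]].rename(columns={"variant_str": "variant"})
        _write(f"labels_{task}.csv", csv.to_csv(index=False))
    return paths
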
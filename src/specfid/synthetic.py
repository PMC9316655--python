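"""Download-free synthetic corpora with a planted fingerprint→spectrum code.

Real MS/MS training resources are large and partly proprietary, so
end-to-end behaviour is exercised on generated corpora in which the
relationship between fingerprint and spectrum is *planted*: each
fingerprint bit excites one or more m/z bins, and a compound's spectrum
is the union of bins excited by its set bits, with configurable additive
intensity noise and bin dropout.  The mapping is many-to-few by default
(several bits may excite one bin), so the learning task is nontrivial
but solvable.  Noiseless, dropout-free generation followed by
preprocessing recovers each fingerprint's support exactly, which anchors
the pipeline's correctness tests.

Compound tables can be built either from a small bundled pool of common
metabolite structures (real chemistry, real fingerprints) or from random
bit vectors with synthetic InChIKeys (no cheminformatics backend in the
loop), with controllable sharing of InChIKey first blocks to exercise
structure-disjoint splitting.

``make_benchmark`` assembles a self-contained miniature of a full
annotation experiment: ~300 compounds, ~1,500 spectra covering all eight
instrument-context cells, a structure-disjoint train/test split, a
candidate database, and a truth table.  Compound masses are drawn in
tight clusters (±2 mDa around ~30 shared centers) so that mass-window
retrieval returns multi-candidate lists and ranking is actually
exercised; mapping bins lie below the smallest precursor so no planted
peak is lost to the super-precursor filter.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import CompoundRecord, write_compound_table
from .fingerprints import TOTAL_BITS, Fingerprint, compute_fingerprints
from .preprocess import ADDUCT_SHIFTS, BinningSpec
from .spectra_io import Peak, SpectrumRecord, write_msp_file
from .evaluate import structure_disjoint_split

#: bundled pool of common metabolite structures (name, SMILES)
SMILES_POOL: tuple[tuple[str, str], ...] = (
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("fructose", "OCC1(O)OCC(O)C(O)C1O"),
    ("sucrose", "OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O"),
    ("alanine", "CC(N)C(O)=O"),
    ("glycine", "NCC(O)=O"),
    ("serine", "OCC(N)C(O)=O"),
    ("leucine", "CC(C)CC(N)C(O)=O"),
    ("phenylalanine", "NC(Cc1ccccc1)C(O)=O"),
    ("tyrosine", "NC(Cc1ccc(O)cc1)C(O)=O"),
    ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(O)=O"),
    ("glutamate", "NC(CCC(O)=O)C(O)=O"),
    ("aspartate", "NC(CC(O)=O)C(O)=O"),
    ("citrate", "OC(=O)CC(O)(CC(O)=O)C(O)=O"),
    ("succinate", "OC(=O)CCC(O)=O"),
    ("fumarate", "OC(=O)/C=C/C(O)=O"),
    ("malate", "OC(CC(O)=O)C(O)=O"),
    ("pyruvate", "CC(=O)C(O)=O"),
    ("lactate", "CC(O)C(O)=O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
    ("adenine", "Nc1ncnc2[nH]cnc12"),
    ("guanine", "Nc1nc2[nH]cnc2c(=O)[nH]1"),
    ("uracil", "O=c1cc[nH]c(=O)[nH]1"),
    ("cytosine", "Nc1cc[nH]c(=O)n1"),
    ("adenosine", "Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O"),
    ("palmitic_acid", "CCCCCCCCCCCCCCCC(O)=O"),
    ("oleic_acid", "CCCCCCCC/C=C\\CCCCCCCC(O)=O"),
    ("citrulline", "NC(CCCNC(N)=O)C(O)=O"),
    ("carnitine", "C[N+](C)(C)CC(O)CC([O-])=O"),
    ("taurine", "NCCS(O)(=O)=O"),
    ("riboflavin", "Cc1cc2nc3c(=O)[nH]c(=O)nc-3n(CC(O)C(O)C(O)CO)c2cc1C"),
    ("niacin", "OC(=O)c1cccnc1"),
)

_POSITIVE_ADDUCTS = tuple(a for a, (_, c) in ADDUCT_SHIFTS.items() if c > 0)
_NEGATIVE_ADDUCTS = tuple(a for a, (_, c) in ADDUCT_SHIFTS.items() if c < 0)
_HIGH_RES_INSTRUMENTS = ("Orbitrap", "Q-TOF")
_LOW_RES_INSTRUMENTS = ("IT", "QqQ")


@dataclass(frozen=True)
class PlantedMapping:
    """The planted code from fingerprint bits to excited m/z bins."""

    assignment: dict[int, tuple[int, ...]]
    base_intensity: float = 100.0
    noise_sd: float = 5.0
    dropout_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")

    def excited_bins(self, bits: np.ndarray) -> set[int]:
        out: set[int] = set()
        for b in np.flatnonzero(bits):
            out.update(self.assignment.get(int(b), ()))
        return out


def make_mapping(
    seed: int,
    n_bits: int = TOTAL_BITS,
    bin_low: int = 50,
    bin_high: int = 490,
    pool_size: int = 440,
    bins_per_bit: int = 1,
    noise_sd: float = 5.0,
    dropout_prob: float = 0.1,
) -> PlantedMapping:
    """Sample a many-to-few bit→bin assignment from a shared bin pool.

    Bins are dealt round-robin from independently shuffled copies of the
    pool, so bin loads are balanced: when ``n_bits * bins_per_bit``
    exceeds the pool size some bins serve several bits (the many-to-few
    regime that makes decoding nontrivial), but no bin is oversubscribed
    by sampling accident.
    """
    rng = np.random.default_rng(seed)
    pool = rng.choice(np.arange(bin_low, bin_high + 1), size=min(pool_size, bin_high - bin_low + 1), replace=False)
    need = n_bits * bins_per_bit
    seq: list[int] = []
    while len(seq) < need:
        seq.extend(int(x) for x in rng.permutation(pool))
    assignment = {
        b: tuple(seq[b * bins_per_bit : (b + 1) * bins_per_bit]) for b in range(n_bits)
    }
    return PlantedMapping(
        assignment=assignment, noise_sd=noise_sd, dropout_prob=dropout_prob, seed=seed
    )


def _synthetic_inchikey(rng: np.random.Generator, block: str | None = None) -> str:
    letters = np.array(list(string.ascii_uppercase))
    if block is None:
        block = "".join(rng.choice(letters, size=14))
    tail = "".join(rng.choice(letters, size=10))
    return f"{block}-{tail}-N"


def generate_compound_table(
    n: int,
    seed: int,
    smiles_pool: "tuple[tuple[str, str], ...] | None" = None,
    prevalence: float = 0.1,
    shared_block_groups: int = 0,
    shared_block_size: int = 2,
    mass_range: tuple[float, float] = (100.0, 1010.0),
    mass_clusters: int | None = None,
    cluster_jitter: float = 0.002,
) -> list[CompoundRecord]:
    """Build a candidate table of ``n`` compounds.

    With a ``smiles_pool``, structures are drawn from the pool (cycled)
    and fingerprints, InChIKeys, formulas and monoisotopic masses are the
    real computed ones.  Without it, fingerprints are random with the
    given per-bit ``prevalence``, InChIKeys are synthetic (optionally
    forcing groups of compounds to share a first block), and masses are
    drawn uniformly from ``mass_range`` — or, when ``mass_clusters`` is
    set, from that many tight cluster centers with ±``cluster_jitter`` Da
    spread, so mass search returns crowded candidate lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if smiles_pool is not None:
        from rdkit import Chem
        from rdkit.Chem.Descriptors import ExactMolWt
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula

        names, smiles = zip(*(smiles_pool[i % len(smiles_pool)] for i in range(n)))
        fps = compute_fingerprints(list(smiles))
        records = []
        for i, (name, smi, fp) in enumerate(zip(names, smiles, fps)):
            mol = Chem.MolFromSmiles(smi)
            records.append(
                CompoundRecord(
                    id=f"{name}_{i}",
                    inchikey=Chem.MolToInchiKey(mol),
                    smiles=smi,
                    formula=CalcMolFormula(mol).replace("+", "").replace("-", ""),
                    monoisotopic_mass=float(ExactMolWt(mol)),
                    fingerprint=fp,
                )
            )
        return records

    lo, hi = mass_range
    if mass_clusters:
        centers = rng.uniform(lo, hi, size=mass_clusters)
        masses = centers[rng.integers(0, mass_clusters, size=n)] + rng.uniform(
            -cluster_jitter, cluster_jitter, size=n
        )
    else:
        masses = rng.uniform(lo, hi, size=n)
    bit_matrix = (rng.random((n, TOTAL_BITS)) < prevalence).astype(np.uint8)
    inchikeys: list[str] = []
    shared = 0
    while len(inchikeys) < n:
        if shared < shared_block_groups:
            block = "".join(rng.choice(np.array(list(string.ascii_uppercase)), size=14))
            for _ in range(min(shared_block_size, n - len(inchikeys))):
                inchikeys.append(_synthetic_inchikey(rng, block))
            shared += 1
        else:
            inchikeys.append(_synthetic_inchikey(rng))
    records = []
    for i in range(n):
        c, h, o, nn = rng.integers(5, 40), rng.integers(6, 60), rng.integers(0, 10), rng.integers(0, 6)
        formula = f"C{c}H{h}" + (f"N{nn}" if nn else "") + (f"O{o}" if o else "")
        records.append(
            CompoundRecord(
                id=f"syn{i:04d}",
                inchikey=inchikeys[i],
                smiles="",
                formula=formula,
                monoisotopic_mass=float(masses[i]),
                fingerprint=Fingerprint(bits=bit_matrix[i], source="computed"),
            )
        )
    return records


def generate_spectra(
    compounds: list[CompoundRecord],
    mapping: PlantedMapping,
    seed: int,
    contexts: dict[int, float] | None = None,
    spectra_per_compound: int = 1,
    corruption: str | None = None,
    precursor_jitter_sd: float = 0.0015,
) -> list[SpectrumRecord]:
    """Emit planted spectra for each compound.

    A spectrum's peaks are the bins excited by the compound's set bits,
    each surviving dropout independently, at intensity ``base ±
    N(0, noise_sd)`` (floored at a small positive value), placed at the
    bin center.  The precursor m/z is the compound mass shifted by an
    adduct sampled for the drawn ionization mode; collision-energy
    strings and instrument types realize the drawn context cell.
    ``contexts`` is a distribution over the 8 cell indices (uniform when
    omitted).  The precursor m/z carries Gaussian measurement error of
    ``precursor_jitter_sd`` Da (default 1.5 mDa, a few ppm at typical
    masses) so mass search does not trivially single out the true
    compound.  ``corruption="few-peaks"`` truncates spectra to two peaks
    so they fail the minimum-peak filter (negative fixtures).
    """
    rng = np.random.default_rng(seed)
    if contexts is None:
        cells, probs = np.arange(8), np.full(8, 1 / 8)
    else:
        cells = np.array(sorted(contexts))
        probs = np.array([contexts[c] for c in cells], dtype=float)
        probs = probs / probs.sum()
    records: list[SpectrumRecord] = []
    for compound in compounds:
        bits = compound.fingerprint.bits
        for rep in range(spectra_per_compound):
            cell = int(rng.choice(cells, p=probs))
            energy_high, res_high, positive = (cell >> 2) & 1, (cell >> 1) & 1, cell & 1
            mode = "positive" if positive else "negative"
            adduct = str(rng.choice(_POSITIVE_ADDUCTS if positive else _NEGATIVE_ADDUCTS))
            shift, _ = ADDUCT_SHIFTS[adduct]
            ce = int(rng.integers(30, 61)) if energy_high else int(rng.integers(10, 30))
            instrument_type = str(
                rng.choice(_HIGH_RES_INSTRUMENTS if res_high else _LOW_RES_INSTRUMENTS)
            )
            excited = sorted(mapping.excited_bins(bits))
            peaks = []
            for b in excited:
                if mapping.dropout_prob > 0 and rng.random() < mapping.dropout_prob:
                    continue
                intensity = mapping.base_intensity + (
                    rng.normal(0.0, mapping.noise_sd) if mapping.noise_sd > 0 else 0.0
                )
                peaks.append(Peak(b + 0.5, max(intensity, 1e-3)))
            if corruption == "few-peaks":
                peaks = peaks[:2]
            records.append(
                SpectrumRecord(
                    peaks=peaks,
                    inchikey=compound.inchikey,
                    smiles=compound.smiles or None,
                    spectrum_id=f"{compound.id}_s{rep}",
                    source="synthetic",
                    ionization_mode=mode,
                    adduct=adduct,
                    precursor_mz=compound.monoisotopic_mass
                    + shift
                    + (rng.normal(0.0, precursor_jitter_sd) if precursor_jitter_sd > 0 else 0.0),
                    exact_mass=compound.monoisotopic_mass,
                    instrument_type=instrument_type,
                    instrument=f"synthetic-{instrument_type}",
                    collision_energy_raw=f"{ce} eV",
                    collision_energy_ev=float(ce),
                    library="synthetic",
                )
            )
    return records


@dataclass
class Benchmark:
    """A miniature annotation experiment: train/test spectra, a candidate
    database, a truth table, and the planted mapping that generated it."""

    compounds: list[CompoundRecord]
    train_records: list[SpectrumRecord]
    test_records: list[SpectrumRecord]
    truth: dict[str, str]  # test spectrum_id -> InChIKey
    mapping: PlantedMapping
    binning: BinningSpec
    train_keys: set[str] = field(default_factory=set)
    test_keys: set[str] = field(default_factory=set)

    @property
    def fingerprints_by_key(self) -> dict[str, Fingerprint]:
        return {c.inchikey: c.fingerprint for c in self.compounds}


def make_benchmark(
    seed: int,
    n_compounds: int = 300,
    spectra_per_compound: int = 5,
    train_fraction: float = 0.8,
    binning: BinningSpec = BinningSpec(),
    noise_sd: float = 5.0,
    dropout_prob: float = 0.1,
    mass_clusters: int = 30,
) -> Benchmark:
    """Build the standard desk-scale benchmark (~300 compounds, ~1,500
    spectra, all eight context cells populated, structure-disjoint split).

    Masses are clustered so candidate lists are crowded (mean length well
    above 1) and compound masses start at 500 Da while mapping bins stay
    below 491, so planted peaks always survive the super-precursor filter.
    """
    compounds = generate_compound_table(
        n_compounds,
        seed=seed,
        prevalence=0.1,
        mass_range=(500.0, 1000.0),
        mass_clusters=mass_clusters,
    )
    mapping = make_mapping(seed=seed + 1, noise_sd=noise_sd, dropout_prob=dropout_prob)
    train_keys, test_keys = structure_disjoint_split(
        [c.inchikey for c in compounds], train_fraction, seed=seed + 2
    )
    by_key = {c.inchikey: c for c in compounds}
    train_records = generate_spectra(
        [by_key[k] for k in sorted(train_keys)],
        mapping,
        seed=seed + 3,
        spectra_per_compound=spectra_per_compound,
    )
    test_records = generate_spectra(
        [by_key[k] for k in sorted(test_keys)],
        mapping,
        seed=seed + 4,
        spectra_per_compound=spectra_per_compound,
    )
    truth = {r.spectrum_id: r.inchikey for r in test_records}
    return Benchmark(
        compounds=compounds,
        train_records=train_records,
        test_records=test_records,
        truth=truth,
        mapping=mapping,
        binning=binning,
        train_keys=train_keys,
        test_keys=test_keys,
    )


def write_corpus(benchmark: Benchmark, directory: str | Path) -> dict:
    """Persist a benchmark as text files: MSP spectra, compound TSV, truth
    TSV, and a manifest; returns the manifest dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_msp_file(benchmark.train_records, directory / "train.msp")
    write_msp_file(benchmark.test_records, directory / "test.msp")
    write_compound_table(benchmark.compounds, directory / "compounds.tsv")
    with open(directory / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("spectrum_id\tinchikey\n")
        for sid, key in sorted(benchmark.truth.items()):
            fh.write(f"{sid}\t{key}\n")
    manifest = {
        "n_compounds": len(benchmark.compounds),
        "n_train_spectra": len(benchmark.train_records),
        "n_test_spectra": len(benchmark.test_records),
        "bin_start": benchmark.binning.bin_start,
        "bin_count": benchmark.binning.bin_count,
        "noise_sd": benchmark.mapping.noise_sd,
        "dropout_prob": benchmark.mapping.dropout_prob,
        "files": ["train.msp", "test.msp", "compounds.tsv", "truth.tsv"],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
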
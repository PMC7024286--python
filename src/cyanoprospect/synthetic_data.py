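"""Synthetic inputs with planted, recoverable structure.

Three generators emulate the statistical shape of the pipeline's real inputs
so every stage can be scored against a known truth table:

* ``simulate_alignment`` — a gapless 16S-like alignment with a planted
  genus/species hierarchy. Sequences descend from a root by independent
  per-site substitution (equal-rate, Jukes-Cantor-like) with branch
  substitution probabilities chosen so realized pairwise p-distances land in
  the requested within-species / within-genus / between-genus bands.
* ``simulate_spectra`` — MS/MS spectral families: members of a family share a
  fixed fraction of fragment peaks (with family-level intensities) and carry a
  per-member precursor mass shift applied to a family-level subset of the
  shared fragments, emulating structural analogs; noise spectra are fully
  random. A quantification table concentrates each family in one genus's
  samples.
* ``simulate_plate`` — OD620 microplate wells where the sample OD is derived
  from a planted inhibition percentage plus Gaussian noise.

All generators are deterministic for a fixed seed, and the truth tables they
return are sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioassay import PlateReading
from .specnet import FragmentSpectrum
from .taxonomy import AlignedSequences

__all__ = [
    "SequenceSimConfig",
    "SpectraSimConfig",
    "PlateSimConfig",
    "SimulationConfig",
    "simulate_alignment",
    "simulate_spectra",
    "simulate_plate",
    "shift_analog",
    "simulate_bundle",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configs


@dataclass
class SequenceSimConfig:
    """Planted taxonomy for the alignment generator.

    Defaults mirror the scale of a small strain-collection study: 7 genera
    holding 12 species and 20 strains, 1300 aligned positions, within-species
    divergence 0.4%, within-genus 3%, between-genus 8%, plus a distant
    outgroup for rooting.
    """

    n_genera: int = 7
    species_per_genus: int | tuple = (2, 2, 2, 2, 2, 1, 1)
    strains_per_species: int | tuple = (2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1)
    seq_length: int = 1300
    within_species_div: float = 0.004
    within_genus_div: float = 0.03
    between_genus_div: float = 0.08
    outgroup: bool = True
    outgroup_div: float = 0.15

    def species_counts(self) -> list[int]:
        if isinstance(self.species_per_genus, int):
            return [self.species_per_genus] * self.n_genera
        if len(self.species_per_genus) != self.n_genera:
            raise ValueError("species_per_genus length must equal n_genera")
        return list(self.species_per_genus)

    def strain_counts(self) -> list[int]:
        n_species = sum(self.species_counts())
        if isinstance(self.strains_per_species, int):
            return [self.strains_per_species] * n_species
        if len(self.strains_per_species) != n_species:
            raise ValueError("strains_per_species length must equal total species")
        return list(self.strains_per_species)


@dataclass
class SpectraSimConfig:
    """Planted spectral families for the networking generator."""

    n_families: int = 5
    spectra_per_family: int = 6
    peaks_per_spectrum: int = 12
    shared_fraction: float = 0.8
    analog_delta: tuple = (10.0, 60.0)  # Da, drawn uniformly per analog
    n_noise_spectra: int = 10
    n_samples: int = 8
    genus_labels: tuple = ("Arthrospira", "Jaaginema", "Oscillatoria", "Scytonema")
    mz_min: float = 50.0
    mz_max: float = 1200.0


@dataclass
class PlateSimConfig:
    """Planted growth inhibition for the microplate generator.

    ``true_inhibition`` may be a single percentage or a mapping
    ``(extract_id, pathogen_id) -> percentage``.
    """

    true_inhibition: float | dict = 60.0
    od_blank: float = 0.05
    od_control: float = 0.65
    noise_sd: float = 0.02
    n_replicates: int = 3
    concentration: float = 100.0


@dataclass
class SimulationConfig:
    seed: int = 0
    sequences: SequenceSimConfig = field(default_factory=SequenceSimConfig)
    spectra: SpectraSimConfig = field(default_factory=SpectraSimConfig)
    plates: PlateSimConfig = field(default_factory=PlateSimConfig)


def _rng(cfg_or_seed, override: int | None) -> np.random.Generator:
    seed = override if override is not None else getattr(cfg_or_seed, "seed", cfg_or_seed)
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# alignments


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute round(p * L) sites, chosen at random, each uniformly to one
    of the 3 other bases.

    Fixing the substitution *count* per branch (rather than flipping a coin per
    site) removes the binomial component of divergence variance, so realized
    pairwise distances stay within a tight band around the planted values even
    for the minimum over many taxon pairs; the residual spread comes only from
    site collisions between branches.
    """
    out = seq.copy()
    n_mut = int(round(p * seq.size))
    if n_mut:
        hit = rng.choice(seq.size, size=n_mut, replace=False)
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + rng.integers(1, 4, size=n_mut)) % 4]
    return out


def simulate_alignment(
    cfg: SimulationConfig | SequenceSimConfig, seed: int | None = None
) -> tuple[AlignedSequences, pd.DataFrame]:
    """Alignment with planted species/genus structure plus its truth table.

    Branch substitution probabilities are half the target pairwise divergence
    at each level, so two strains separated at a level show approximately the
    configured divergence (back-substitutions bias this down by O(div^2),
    well inside a 20% relative band at these depths).
    """
    if isinstance(cfg, SimulationConfig):
        scfg, seed = cfg.sequences, cfg.seed if seed is None else seed
    else:
        scfg = cfg
    if not scfg.within_species_div <= scfg.within_genus_div <= scfg.between_genus_div:
        raise ValueError(
            "divergences must be ordered within_species <= within_genus <= between_genus"
        )
    rng = _rng(scfg, seed)
    a = scfg.within_species_div / 2.0  # strain branch
    b = (scfg.within_genus_div - scfg.within_species_div) / 2.0  # species branch
    c = (scfg.between_genus_div - scfg.within_genus_div) / 2.0  # genus branch

    root = _BASES[rng.integers(0, 4, size=scfg.seq_length)]
    records, rows = [], []
    species_counts = scfg.species_counts()
    strain_counts = scfg.strain_counts()
    sp_global = 0
    for g in range(scfg.n_genera):
        genus_anc = _mutate(root, c, rng)
        for _s in range(species_counts[g]):
            sp_global += 1
            species_anc = _mutate(genus_anc, b, rng)
            for r in range(strain_counts[sp_global - 1]):
                strain = _mutate(species_anc, a, rng)
                sid = f"strain_g{g + 1:02d}_s{sp_global:02d}_r{r + 1}"
                records.append((sid, strain.tobytes().decode("ascii")))
                rows.append((sid, g + 1, sp_global, False))
    if scfg.outgroup:
        # the outgroup branch alone carries most of the outgroup divergence
        out_branch = max(scfg.outgroup_div - (a + b + c), 0.0)
        og = _mutate(root, out_branch, rng)
        records.append(("OUTGROUP", og.tobytes().decode("ascii")))
        rows.append(("OUTGROUP", 0, 0, True))
    truth = pd.DataFrame(rows, columns=["id", "genus", "species", "is_outgroup"])
    return AlignedSequences(records), truth


# ---------------------------------------------------------------------------
# spectra


def _draw_mz(rng, n, lo, hi, existing=(), min_gap=1.0):
    """n m/z values on a 0.01 Da grid with pairwise separation >= min_gap."""
    taken = list(existing)
    out = []
    for _ in range(10000):
        if len(out) == n:
            break
        m = np.round(rng.uniform(lo, hi), 2)
        if all(abs(m - t) >= min_gap for t in taken):
            out.append(m)
            taken.append(m)
    if len(out) < n:
        raise RuntimeError("could not place peaks with the requested separation")
    return np.array(sorted(out))


def shift_analog(
    spec: FragmentSpectrum, delta: float, fraction: float = 0.5
) -> FragmentSpectrum:
    """A structural-analog spectrum: precursor and the lowest ``fraction`` of
    fragments shifted by ``delta`` Da (deterministic choice by m/z order)."""
    n_shift = int(round(fraction * spec.n_peaks))
    mz = spec.mz.copy()
    mz[:n_shift] = mz[:n_shift] + delta
    return replace(spec, feature_id=spec.feature_id + "_analog",
                   precursor_mz=spec.precursor_mz + delta, mz=mz,
                   intensity=spec.intensity.copy())


def simulate_spectra(
    cfg: SimulationConfig | SpectraSimConfig, seed: int | None = None
) -> tuple[list[FragmentSpectrum], pd.DataFrame, pd.DataFrame]:
    """Spectral families, a quantification table, and the truth table.

    Family members share ``shared_fraction`` of a family base peak set at
    family-level intensities; the rest of each member's peaks are resampled at
    lower intensity. Every member beyond the first is an analog: its precursor
    and a family-level "modifiable" subset (half) of the shared fragments are
    shifted by a per-member delta drawn from ``analog_delta``. Noise spectra
    are fully random. Precursor intensities concentrate each family in the
    samples of one genus.

    Returns ``(spectra, quant, truth)``; ``quant`` has feature ids as rows and
    sample ids as columns, ``truth`` records family, analog delta and the
    genus each family is planted in.
    """
    if isinstance(cfg, SimulationConfig):
        mcfg, seed = cfg.spectra, cfg.seed if seed is None else seed
    else:
        mcfg = cfg
    if not 0.0 <= mcfg.shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    n_shared = int(round(mcfg.shared_fraction * mcfg.peaks_per_spectrum))
    if n_shared < 7:
        import warnings

        warnings.warn(
            "shared_fraction * peaks_per_spectrum < 7: planted families may not "
            "reach the matched-peak floor for network edges",
            stacklevel=2,
        )
    rng = _rng(mcfg, seed)
    samples = [f"S{i + 1:02d}" for i in range(mcfg.n_samples)]
    sample_genus = {s: mcfg.genus_labels[i % len(mcfg.genus_labels)]
                    for i, s in enumerate(samples)}

    spectra, rows, quant_rows = [], [], {}
    for fam in range(1, mcfg.n_families + 1):
        precursor = np.round(rng.uniform(400.0, 900.0), 2)
        base_mz = _draw_mz(rng, mcfg.peaks_per_spectrum, mcfg.mz_min, precursor - 60.0)
        base_int = rng.lognormal(mean=3.0, sigma=0.6, size=mcfg.peaks_per_spectrum)
        shared_idx = np.sort(rng.choice(mcfg.peaks_per_spectrum, n_shared, replace=False))
        mod_idx = shared_idx[: n_shared // 2]  # family-level modifiable subset
        genus = mcfg.genus_labels[(fam - 1) % len(mcfg.genus_labels)]
        genus_samples = [s for s in samples if sample_genus[s] == genus]
        for m in range(mcfg.spectra_per_family):
            lo, hi = mcfg.analog_delta
            delta = 0.0 if m == 0 else float(np.round(rng.uniform(lo, hi), 2))
            mz = base_mz.copy()
            intensity = base_int.copy()
            free = np.setdiff1d(np.arange(mcfg.peaks_per_spectrum), shared_idx)
            if free.size:
                mz[free] = _draw_mz(rng, free.size, mcfg.mz_min, precursor - 60.0,
                                    existing=mz[shared_idx])
                intensity[free] = 0.3 * rng.lognormal(mean=3.0, sigma=0.6, size=free.size)
            mz[mod_idx] = mz[mod_idx] + delta
            fid = f"F{fam:02d}_{m + 1:02d}"
            intensities = {
                s: (float(rng.lognormal(mean=12.0, sigma=0.4)) if s in genus_samples else 0.0)
                for s in samples
            }
            spectra.append(FragmentSpectrum(
                feature_id=fid, precursor_mz=float(precursor + delta),
                mz=mz, intensity=intensity, rt=float(np.round(rng.uniform(1, 20), 2)),
                sample_intensities=intensities,
            ))
            rows.append((fid, fam, delta, genus))
            quant_rows[fid] = intensities
    for k in range(1, mcfg.n_noise_spectra + 1):
        precursor = np.round(rng.uniform(300.0, 1100.0), 2)
        mz = _draw_mz(rng, mcfg.peaks_per_spectrum, mcfg.mz_min, precursor - 60.0)
        intensity = rng.lognormal(mean=3.0, sigma=0.6, size=mcfg.peaks_per_spectrum)
        fid = f"N{k:02d}"
        home = samples[int(rng.integers(0, len(samples)))]
        intensities = {s: (float(rng.lognormal(mean=11.0, sigma=0.4)) if s == home else 0.0)
                       for s in samples}
        spectra.append(FragmentSpectrum(
            feature_id=fid, precursor_mz=float(precursor), mz=mz, intensity=intensity,
            rt=float(np.round(rng.uniform(1, 20), 2)), sample_intensities=intensities,
        ))
        rows.append((fid, 0, 0.0, sample_genus[home]))
        quant_rows[fid] = intensities
    truth = pd.DataFrame(rows, columns=["feature_id", "family", "analog_delta", "genus"])
    quant = pd.DataFrame.from_dict(quant_rows, orient="index", columns=samples)
    quant.index.name = "feature_id"
    return spectra, quant, truth


# ---------------------------------------------------------------------------
# plates


def simulate_plate(
    cfg: SimulationConfig | PlateSimConfig, seed: int | None = None
) -> tuple[list[PlateReading], pd.DataFrame]:
    """Microplate readings with planted inhibition plus their truth table.

    Per replicate, ``od_sample = B + (1 - p/100) * (T - B) + N(0, noise_sd)``
    truncated at zero; control and blank wells are read noise-free so the
    planted value is exactly recoverable at ``noise_sd = 0``.
    """
    if isinstance(cfg, SimulationConfig):
        pcfg, seed = cfg.plates, cfg.seed if seed is None else seed
    else:
        pcfg = cfg
    if pcfg.od_control <= pcfg.od_blank:
        raise ValueError("od_control must exceed od_blank")
    rng = _rng(pcfg, seed)
    planted = pcfg.true_inhibition
    if not isinstance(planted, dict):
        planted = {("EXT1", "P_atlantica"): float(planted)}
    readings, rows = [], []
    for (extract, pathogen), p in sorted(planted.items()):
        wells = []
        for _ in range(pcfg.n_replicates):
            ods = (pcfg.od_blank
                   + (1.0 - p / 100.0) * (pcfg.od_control - pcfg.od_blank)
                   + rng.normal(0.0, pcfg.noise_sd))
            wells.append((max(ods, 0.0), pcfg.od_control, pcfg.od_blank))
        readings.append(PlateReading(extract, pathogen, wells, pcfg.concentration))
        rows.append((extract, pathogen, p))
    truth = pd.DataFrame(rows, columns=["extract_id", "pathogen_id", "true_inhibition"])
    return readings, truth


# ---------------------------------------------------------------------------
# bundle


def simulate_bundle(cfg: SimulationConfig, outdir) -> dict:
    """Write a full synthetic input set in the formats the pipeline consumes.

    Emits aligned FASTA, MGF + quantification CSV + sample-to-genus map, plate
    CSV, and truth-table CSVs; returns the path map.
    """
    from pathlib import Path

    from .bioassay import write_plate_csv
    from .specnet import write_mgf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, seq_truth = simulate_alignment(cfg)
    spectra, quant, spec_truth = simulate_spectra(cfg)
    readings, plate_truth = simulate_plate(cfg)

    paths = {
        "fasta": outdir / "alignment.fasta",
        "mgf": outdir / "features.mgf",
        "quant": outdir / "feature_quant.csv",
        "sample_genus": outdir / "sample_genus.csv",
        "plates": outdir / "plates.csv",
        "seq_truth": outdir / "truth_sequences.csv",
        "spec_truth": outdir / "truth_spectra.csv",
        "plate_truth": outdir / "truth_plates.csv",
    }
    aln.to_fasta(paths["fasta"])
    write_mgf(spectra, paths["mgf"])
    quant.to_csv(paths["quant"])
    mcfg = cfg.spectra
    samples = list(quant.columns)
    pd.DataFrame({
        "sample_id": samples,
        "genus": [mcfg.genus_labels[i % len(mcfg.genus_labels)] for i in range(len(samples))],
    }).to_csv(paths["sample_genus"], index=False)
    write_plate_csv(readings, paths["plates"])
    seq_truth.to_csv(paths["seq_truth"], index=False)
    spec_truth.to_csv(paths["spec_truth"], index=False)
    plate_truth.to_csv(paths["plate_truth"], index=False)
    return paths
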
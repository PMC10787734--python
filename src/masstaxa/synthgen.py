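"""Synthetic fingerprint libraries with hierarchical taxonomic structure.

The generator emulates the structure of a curated MALDI-TOF reference
library of metazoan specimens: many species nested in genera, classes
and phyla; each species defined by a reproducible set of peak masses in
the 2-10 kDa fingerprint range, part inherited from its higher taxa
(phylum/class/genus-shared peaks) and part species-specific; several
specimens per species measured in 2-3 technical replicates.

A simulated measurement places Gaussian-shaped peaks (with per-specimen
lognormal intensity multipliers, Bernoulli peak dropout and ppm-scale
mass jitter) on a smooth exponentially decaying chemical baseline
``a * exp(-b * m)`` plus additive Gaussian detector noise, sampled on a
uniform mass grid. All randomness derives from ``SimParams.seed`` plus
the (species, specimen, replicate) coordinates, so every spectrum is
individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import RawSpectrum, TaxonLabel

__all__ = [
    "SpeciesProfile",
    "SimParams",
    "make_taxonomy_profiles",
    "simulate_spectrum",
    "simulate_library",
    "preset_params",
]


@dataclass
class SpeciesProfile:
    """Ground-truth fingerprint of one species."""

    taxon: TaxonLabel
    peak_masses: np.ndarray
    base_intensities: np.ndarray
    # indices into peak_masses by inheritance level, for scenario building
    level_of_peak: np.ndarray = field(default_factory=lambda: np.array([], dtype="U8"))
    sex_specific_masses: dict | None = None
    sex_specific_intensities: dict | None = None

    def __post_init__(self) -> None:
        self.peak_masses = np.asarray(self.peak_masses, dtype=float)
        self.base_intensities = np.asarray(self.base_intensities, dtype=float)
        if len(self.peak_masses) != len(self.base_intensities):
            raise ValueError("peak_masses and base_intensities differ in length")
        if np.any(self.base_intensities <= 0):
            raise ValueError("base intensities must be positive")


@dataclass
class SimParams:
    """Study-design and instrument parameters of the simulator.

    Taxonomic design defaults give 20 species (2 phyla x 2 classes x 5
    genera x 1 species) with 8 specimens each and 2 technical replicates —
    a desk-scale analogue of a multi-phylum reference library. Peak
    counts per inheritance level, the lognormal intensity coefficient of
    variation (0.5), per-peak dropout (0.15) and ~200 ppm mass jitter
    reflect the strong intra-species intensity variability and occasional
    peak absence typical of soft-ionization fingerprints; the baseline
    emulates the raised low-mass chemical background of matrix clusters.
    """

    n_phyla: int = 2
    n_classes_per_phylum: int = 2
    n_genera_per_class: int = 5
    n_species_per_genus: int = 1
    n_specimens_per_species: int = 8
    n_replicates: int = 2
    n_phylum_peaks: int = 12
    n_class_peaks: int = 20
    n_genus_peaks: int = 6
    n_species_peaks: int = 40
    intensity_cv: float = 0.5
    dropout_p: float = 0.15
    mass_jitter_ppm: float = 200.0
    baseline_a: float = 2.0
    baseline_b: float = 2.5e-4
    noise_sd: float = 0.02
    points_per_spectrum: int = 7001
    mass_range: tuple = (2000.0, 16000.0)
    peak_mass_range: tuple = (2100.0, 15500.0)
    min_peak_separation: float = 50.0
    peak_sigma: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_phyla", "n_classes_per_phylum", "n_genera_per_class",
                     "n_species_per_genus", "n_specimens_per_species",
                     "n_replicates", "n_phylum_peaks", "n_class_peaks",
                     "n_genus_peaks", "n_species_peaks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout_p <= 1:
            raise ValueError("dropout_p must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_species(self) -> int:
        return (self.n_phyla * self.n_classes_per_phylum
                * self.n_genera_per_class * self.n_species_per_genus)


def _species_key(species: str) -> int:
    return zlib.crc32(species.encode()) & 0x7FFFFFFF


def _draw_separated_masses(rng: np.random.Generator, n: int,
                           lo: float, hi: float, sep: float,
                           avoid: np.ndarray | None = None) -> np.ndarray:
    """n masses in [lo, hi] keeping pairwise separation >= sep.

    Separation is enforced among the drawn masses and against ``avoid``
    (a species' inherited peaks) by rejection sampling.
    """
    if (n - 1) * sep >= (hi - lo):
        raise ValueError(
            f"cannot place {n} peaks with separation {sep} Da in "
            f"[{lo}, {hi}] Da")
    taken = list(np.atleast_1d(avoid)) if avoid is not None and len(np.atleast_1d(avoid)) else []
    n_avoid = len(taken)
    tries = 0
    while len(taken) - n_avoid < n:
        m = rng.uniform(lo, hi)
        if all(abs(m - t) >= sep for t in taken):
            taken.append(m)
        tries += 1
        if tries > 10000 * (n + 1):
            raise ValueError(
                f"cannot place {n} peaks with separation {sep} Da in "
                f"[{lo}, {hi}] Da avoiding {n_avoid} existing masses")
    return np.sort(np.asarray(taken[n_avoid:]))


def make_taxonomy_profiles(params: SimParams) -> list[SpeciesProfile]:
    """Build hierarchical species profiles with peak inheritance.

    Every species' mass set is the union of its phylum-, class- and
    genus-shared peaks and its own species-specific peaks, all pairwise
    separated by at least ``min_peak_separation`` *within the species*
    (the instrument-resolution constraint); masses of unrelated lineages
    may coincide, as in real libraries. Shared peaks carry a shared
    typical intensity (mildly modulated per species) so that
    higher-taxon signal survives in relative intensities as well as in
    peak presence.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 941])
    lo, hi = params.peak_mass_range
    sep = params.min_peak_separation

    def draw(k: int, avoid=None) -> np.ndarray:
        return _draw_separated_masses(rng, k, lo, hi, sep, avoid=avoid)

    def base_int(k: int) -> np.ndarray:
        return rng.uniform(0.3, 1.0, k)

    profiles: list[SpeciesProfile] = []
    for p in range(params.n_phyla):
        ph_masses, ph_int = draw(params.n_phylum_peaks), base_int(params.n_phylum_peaks)
        for c in range(params.n_classes_per_phylum):
            cl_masses = draw(params.n_class_peaks, avoid=ph_masses)
            cl_int = base_int(params.n_class_peaks)
            for g in range(params.n_genera_per_class):
                ge_masses = draw(params.n_genus_peaks,
                                 avoid=np.concatenate([ph_masses, cl_masses]))
                ge_int = base_int(params.n_genus_peaks)
                inherited = np.concatenate([ph_masses, cl_masses, ge_masses])
                for s in range(params.n_species_per_genus):
                    sp_masses = draw(params.n_species_peaks, avoid=inherited)
                    sp_int = base_int(params.n_species_peaks)
                    masses = np.concatenate([ph_masses, cl_masses, ge_masses, sp_masses])
                    # shared peaks keep their level intensity up to a mild
                    # per-species modulation
                    mod = rng.lognormal(0.0, 0.15, len(masses) - len(sp_masses))
                    inten = np.concatenate([
                        np.concatenate([ph_int, cl_int, ge_int]) * mod, sp_int])
                    levels = np.array(
                        ["phylum"] * len(ph_masses) + ["class"] * len(cl_masses)
                        + ["genus"] * len(ge_masses) + ["species"] * len(sp_masses))
                    order = np.argsort(masses)
                    taxon = TaxonLabel(
                        species=f"P{p}C{c}G{g}_sp{s}",
                        genus=f"P{p}C{c}_gen{g}",
                        class_=f"P{p}_cls{c}",
                        phylum=f"phy{p}")
                    profiles.append(SpeciesProfile(
                        taxon=taxon, peak_masses=masses[order],
                        base_intensities=inten[order],
                        level_of_peak=levels[order]))
    return profiles


def simulate_spectrum(profile: SpeciesProfile, params: SimParams,
                      specimen_idx: int, replicate_idx: int) -> RawSpectrum:
    """One measurement of one specimen.

    Specimen-level randomness (intensity multipliers, peak dropout, sex)
    is shared across technical replicates of the specimen; jitter and
    detector noise are redrawn per replicate. Everything is a pure
    function of ``(params.seed, species, specimen_idx, replicate_idx)``.
    """
    params.validate()
    key = _species_key(profile.taxon.species)
    rng_spec = np.random.default_rng([params.seed, key, specimen_idx])
    rng_rep = np.random.default_rng([params.seed, key, specimen_idx, replicate_idx])

    masses = profile.peak_masses
    base = profile.base_intensities
    sex = ""
    if profile.sex_specific_masses:
        sexes = sorted(profile.sex_specific_masses)
        sex = sexes[specimen_idx % len(sexes)]
        masses = np.concatenate([masses, profile.sex_specific_masses[sex]])
        extra_int = (profile.sex_specific_intensities or {}).get(
            sex, np.ones(len(profile.sex_specific_masses[sex])))
        base = np.concatenate([base, extra_int])

    sigma_ln = np.sqrt(np.log1p(params.intensity_cv ** 2))
    mult = rng_spec.lognormal(-0.5 * sigma_ln ** 2, sigma_ln, len(masses))
    present = rng_spec.random(len(masses)) >= params.dropout_p

    grid = np.linspace(params.mass_range[0], params.mass_range[1],
                       params.points_per_spectrum)
    step = grid[1] - grid[0]
    y = params.baseline_a * np.exp(-params.baseline_b * grid)
    amp = base * mult
    jitter = rng_rep.normal(0.0, params.mass_jitter_ppm * 1e-6 * masses)
    centers = masses + jitter
    s = params.peak_sigma
    for m0, a in zip(centers[present], amp[present]):
        j0 = max(0, int((m0 - 5 * s - grid[0]) / step))
        j1 = min(len(grid), int((m0 + 5 * s - grid[0]) / step) + 2)
        y[j0:j1] += a * np.exp(-0.5 * ((grid[j0:j1] - m0) / s) ** 2)
    if params.noise_sd > 0:
        y = y + rng_rep.normal(0.0, params.noise_sd, len(grid))
    np.clip(y, 0.0, None, out=y)
    taxon = replace(profile.taxon, sex=sex) if sex else profile.taxon
    return RawSpectrum(
        masses=grid, intensities=y,
        specimen_id=f"{profile.taxon.species}_s{specimen_idx:03d}",
        replicate_id=f"r{replicate_idx}", taxon=taxon)


def true_peaks_of(profile: SpeciesProfile, params: SimParams,
                  specimen_idx: int) -> np.ndarray:
    """Masses of the peaks actually present (not dropped) in a specimen.

    Reuses the specimen-level RNG stream of :func:`simulate_spectrum`, so
    it reports the simulator's own ground truth for recovery checks.
    """
    key = _species_key(profile.taxon.species)
    rng_spec = np.random.default_rng([params.seed, key, specimen_idx])
    masses = profile.peak_masses
    if profile.sex_specific_masses:
        sexes = sorted(profile.sex_specific_masses)
        sex = sexes[specimen_idx % len(sexes)]
        masses = np.concatenate([masses, profile.sex_specific_masses[sex]])
    sigma_ln = np.sqrt(np.log1p(params.intensity_cv ** 2))
    rng_spec.lognormal(-0.5 * sigma_ln ** 2, sigma_ln, len(masses))  # skip mult draw
    present = rng_spec.random(len(masses)) >= params.dropout_p
    return masses[present]


def simulate_library(params: SimParams,
                     profiles: list[SpeciesProfile] | None = None
                     ) -> tuple[list[RawSpectrum], pd.DataFrame]:
    """Full species x specimens x replicates crossing plus a manifest.

    The manifest matches the reader schema (specimen_id, replicate_id,
    file, species, genus, class, phylum); the ``file`` column holds the
    name a CSV export of the spectrum would get.
    """
    params.validate()
    if profiles is None:
        profiles = make_taxonomy_profiles(params)
    spectra: list[RawSpectrum] = []
    rows = []
    for prof in profiles:
        for i in range(params.n_specimens_per_species):
            for r in range(params.n_replicates):
                s = simulate_spectrum(prof, params, i, r)
                spectra.append(s)
                rows.append({
                    "specimen_id": s.specimen_id, "replicate_id": s.replicate_id,
                    "file": f"{s.specimen_id}_{s.replicate_id}.csv",
                    "species": s.taxon.species, "genus": s.taxon.genus,
                    "class": s.taxon.class_, "phylum": s.taxon.phylum})
    return spectra, pd.DataFrame(rows)


def preset_params(name: str, seed: int = 0) -> tuple[SimParams, list[SpeciesProfile]]:
    """Named scenarios used throughout testing and the worked examples.

    default
        The 20-species multi-phylum reference library.
    hierarchy
        2 phyla x 2 classes x 2 genera x 2 species (16 species) with
        strong class-shared peaks — exercises higher-taxon fallback and
        congeneric affinity.
    cryptic
        Two species with identical peak masses whose base intensities
        differ >= 2x on half the peaks — separable only by intensity
        pattern.
    sex
        One species with sex-exclusive masses plus shared intensity-
        shifted masses, and an outgroup species.
    low_intensity
        Species-specific peaks deliberately faint (informative signals
        near the detection limit) — exercises SNR optimization.
    hard
        Few specific peaks, high variability — exercises reference-
        library sizing (specimens-per-species saturation).
    """
    if name == "default":
        p = SimParams(seed=seed)
        return p, make_taxonomy_profiles(p)
    if name == "hierarchy":
        p = SimParams(seed=seed, n_phyla=2, n_classes_per_phylum=2,
                      n_genera_per_class=2, n_species_per_genus=2,
                      n_class_peaks=8, n_species_peaks=4,
                      n_specimens_per_species=6, n_replicates=1)
        return p, make_taxonomy_profiles(p)
    if name == "cryptic":
        p = SimParams(seed=seed, n_phyla=1, n_classes_per_phylum=1,
                      n_genera_per_class=1, n_species_per_genus=2,
                      n_species_peaks=10, n_specimens_per_species=8,
                      intensity_cv=0.3, dropout_p=0.0)
        base_prof = make_taxonomy_profiles(p)[0]
        rng = np.random.default_rng([seed, 7171])
        ratio = np.ones(len(base_prof.peak_masses))
        half = rng.choice(len(ratio), len(ratio) // 2, replace=False)
        ratio[half] = rng.uniform(2.0, 4.0, len(half))
        t = base_prof.taxon
        prof_a = replace(base_prof, taxon=replace(t, species=t.species + "a"))
        prof_b = replace(base_prof, taxon=replace(t, species=t.species + "b"),
                         base_intensities=base_prof.base_intensities * ratio)
        return p, [prof_a, prof_b]
    if name == "sex":
        p = SimParams(seed=seed, n_phyla=1, n_classes_per_phylum=1,
                      n_genera_per_class=2, n_species_per_genus=1,
                      n_specimens_per_species=10, dropout_p=0.05)
        profs = make_taxonomy_profiles(p)
        rng = np.random.default_rng([seed, 8282])
        target, outgroup = profs
        fm = _draw_separated_masses(rng, 3, 10000.0, 11000.0, 50.0)
        mm = _draw_separated_masses(rng, 3, 11100.0, 12100.0, 50.0)
        target = replace(
            target,
            sex_specific_masses={"F": fm, "M": mm},
            sex_specific_intensities={"F": np.full(3, 0.8), "M": np.full(3, 0.8)})
        return p, [target, outgroup]
    if name == "low_intensity":
        p = SimParams(seed=seed, n_phyla=1, n_classes_per_phylum=1,
                      n_genera_per_class=8, n_species_per_genus=1,
                      n_specimens_per_species=6, n_replicates=1,
                      n_genus_peaks=2, n_species_peaks=6,
                      intensity_cv=0.3, dropout_p=0.05)
        profiles = make_taxonomy_profiles(p)
        out = []
        for prof in profiles:
            inten = prof.base_intensities.copy()
            # genus peaks are species-identifying here (one species per
            # genus), so they are faint alongside the species peaks
            specific = np.isin(prof.level_of_peak, ("genus", "species"))
            inten[specific] = np.clip(inten[specific] * 0.18, 0.02, None)
            inten[~specific] = np.clip(inten[~specific], 0.6, None)
            out.append(replace(prof, base_intensities=inten))
        return p, out
    if name == "hard":
        p = SimParams(seed=seed, n_phyla=1, n_classes_per_phylum=1,
                      n_genera_per_class=6, n_species_per_genus=1,
                      n_specimens_per_species=12, n_replicates=1,
                      n_phylum_peaks=10, n_class_peaks=10, n_genus_peaks=1,
                      n_species_peaks=4, intensity_cv=0.9, dropout_p=0.25,
                      noise_sd=0.03)
        return p, make_taxonomy_profiles(p)
    raise ValueError(f"unknown preset '{name}'")
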
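"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with a known answer
planted in it: taxon tables with a known generating Shannon diversity, LC-MS
feature lists with a known group structure, fingerprint band tables with known
clone membership, MS/MS spectra with known compound families, and fraction
plates with known active windows.  All generators are deterministic under a
fixed seed, and each returns machine-readable truth alongside the data so
downstream recovery tests consume only the data until assertion time.

Noise models are deliberately the simplest adequate ones: Dirichlet-multinomial
read counts, Bernoulli band flips, Gaussian OD noise, log-normal intensity
jitter.  Chromatographic peak shapes, isotope envelopes and read-level
sequence noise are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chemgroup import FeatureList
from .derep import FractionPlate, FractionScheme
from .diversity import CommunityProfile
from .network import MsmsSpectrum, write_mgf

__all__ = [
    "gen_community",
    "gen_feature_tables",
    "gen_fingerprints",
    "gen_compound_family",
    "gen_random_spectra",
    "gen_fraction_plate",
    "study_scale",
    "generate_scenario",
]

CH2 = 14.01565  # methylene homologue spacing in Da


def gen_community(
    n_taxa: int,
    total_reads: int,
    concentration: float,
    seed: int,
    sample_id: str = "synthetic",
) -> tuple[CommunityProfile, float]:
    """Dirichlet-multinomial community with a known generating Shannon index.

    Taxon proportions are drawn from a symmetric Dirichlet(``concentration``);
    large concentration approaches a uniform community (H -> ln n_taxa), small
    concentration gives a skewed one.  Reads are multinomial.  Returns the
    profile and the *generating* distribution's Shannon index in nats.
    """
    if n_taxa < 1 or total_reads < 1:
        raise ValueError("n_taxa and total_reads must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    if n_taxa == 1:
        p = np.array([1.0])
    else:
        p = rng.dirichlet(np.full(n_taxa, concentration))
    counts = rng.multinomial(total_reads, p)
    nz = p[p > 0]
    true_shannon = float(-(nz * np.log(nz)).sum())
    profile = CommunityProfile(
        sample_id=sample_id,
        counts={f"taxon_{i + 1:03d}": int(c) for i, c in enumerate(counts)},
    )
    return profile, true_shannon


def gen_feature_tables(
    n_groups: int = 8,
    samples_per_group: list[int] | int = 8,
    n_buckets: int = 200,
    within_share: float = 0.95,
    between_share: float = 0.05,
    intensity_cv: float = 0.1,
    n_sparse_samples: int = 0,
    seed: int = 0,
    rt_range: tuple[float, float] = (30.0, 1080.0),
    mz_range: tuple[float, float] = (100.0, 1600.0),
) -> tuple[list[FeatureList], dict[str, int]]:
    """LC-MS feature lists with planted metabolic groups.

    Each group owns a template of ``n_buckets`` feature positions; a fraction
    ``between_share`` of every template comes from a pool shared across all
    groups, the rest is group-specific.  A sample inherits the group core — a
    ``within_share`` fraction of the template, identical for all group members
    so any two of them share that fraction of their buckets by construction —
    plus its own private noise buckets for the remainder, with log-normal
    intensity jitter of coefficient of variation ``intensity_cv`` throughout.
    Optional sparse samples (< 50 features) emulate failed injections that the
    feature-count filter should remove.  Returns (feature lists, planted
    group label per sample; sparse samples labelled 0).
    """
    if not 0 <= between_share < within_share <= 1:
        raise ValueError("need 0 <= between_share < within_share <= 1 "
                         "(structure unrecoverable otherwise)")
    if isinstance(samples_per_group, int):
        samples_per_group = [samples_per_group] * n_groups
    if len(samples_per_group) != n_groups:
        raise ValueError("samples_per_group length must equal n_groups")
    rng = np.random.default_rng(seed)

    def draw_positions(n: int) -> np.ndarray:
        rt = rng.uniform(rt_range[0], rt_range[1] - 1e-6, n)
        mz = rng.uniform(mz_range[0], mz_range[1] - 1e-6, n)
        return np.column_stack([rt, mz])

    n_shared = int(round(between_share * n_buckets))
    n_core = int(round(within_share * n_buckets))
    n_private = n_buckets - n_core
    shared_pool = draw_positions(n_shared)
    templates = []
    for _ in range(n_groups):
        own = draw_positions(n_buckets - n_shared)
        positions = np.vstack([shared_pool, own]) if n_shared else own
        core = positions[:n_core]
        base_intensity = rng.uniform(1e4, 1e5, n_core)
        templates.append((core, base_intensity))

    sigma = np.sqrt(np.log1p(intensity_cv**2))
    feature_lists: list[FeatureList] = []
    truth: dict[str, int] = {}
    sample_no = 0
    for g, n_samples in enumerate(samples_per_group, start=1):
        core, base = templates[g - 1]
        for _ in range(n_samples):
            sample_no += 1
            sid = f"S{sample_no:03d}"
            jitter = rng.lognormal(-sigma**2 / 2.0, sigma, n_core)
            private = draw_positions(n_private)
            df = pd.DataFrame(
                {
                    "rt_s": np.concatenate([core[:, 0], private[:, 0]]),
                    "mz": np.concatenate([core[:, 1], private[:, 1]]),
                    "intensity": np.concatenate(
                        [base * jitter, rng.uniform(1e3, 1e4, n_private)]
                    ),
                }
            )
            feature_lists.append(FeatureList(sample_id=sid, features=df))
            truth[sid] = g
    for _ in range(n_sparse_samples):
        sample_no += 1
        sid = f"S{sample_no:03d}"
        pos = draw_positions(20)
        df = pd.DataFrame({"rt_s": pos[:, 0], "mz": pos[:, 1],
                           "intensity": rng.uniform(1e3, 1e4, 20)})
        feature_lists.append(FeatureList(sample_id=sid, features=df))
        truth[sid] = 0
    return feature_lists, truth


def gen_fingerprints(
    n_clones: int = 3,
    copies_per_clone: int = 3,
    n_registry_bands: int = 30,
    flip_prob: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, list[float]], dict[str, int]]:
    """Fingerprint band tables as c clones x m noisy copies.

    Registry band sizes are spaced > 4% apart (safely beyond the default 2%
    registration tolerance); each clone template includes each band with
    probability 0.5, and every copy flips each band's presence independently
    with ``flip_prob``.  Returns (strain -> band sizes in bp, strain -> clone).
    """
    if not 0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    # geometric spacing from 100 bp with >= 4% multiplicative gaps
    sizes = 100.0 * np.cumprod(rng.uniform(1.05, 1.18, n_registry_bands))
    templates = []
    for _ in range(n_clones):
        t = rng.random(n_registry_bands) < 0.5
        if not t.any():
            t[rng.integers(n_registry_bands)] = True
        templates.append(t)
    raw: dict[str, list[float]] = {}
    truth: dict[str, int] = {}
    for c, template in enumerate(templates, start=1):
        for m in range(1, copies_per_clone + 1):
            strain = f"clone{c:02d}_copy{m}"
            present = template ^ (rng.random(n_registry_bands) < flip_prob)
            if not present.any():
                present[np.flatnonzero(template)[0]] = True
            # sub-tolerance sizing noise (+-0.5%)
            noisy = sizes[present] * rng.uniform(0.995, 1.005, present.sum())
            raw[strain] = [round(float(s), 1) for s in noisy]
            truth[strain] = c
    return raw, truth


def gen_compound_family(
    scaffold_peaks: int = 10,
    n_derivatives: int = 7,
    loss_step: float = CH2,
    base_precursor: float = 515.33,
    n_unique_peaks: int = 3,
    seed: int = 0,
    family_id: str = "fam",
) -> tuple[list[MsmsSpectrum], dict[str, str]]:
    """An MS/MS compound family: derivatives sharing a fragment scaffold.

    Derivatives share ``scaffold_peaks`` exact fragment masses (intensities
    re-drawn per derivative) and differ by cumulative homologue steps in the
    precursor (default CH2 = 14.01565 Da), plus a few low-intensity
    derivative-specific peaks.  All intensities sit above the default read
    floor of 1000.  Returns (spectra, spectrum id -> family id).
    """
    if scaffold_peaks < 6:
        import warnings

        warnings.warn(
            "scaffold smaller than 6 peaks: family undetectable at the "
            "default >= 6 matched-fragment rule",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    scaffold_mz = np.sort(rng.uniform(100.0, base_precursor - 30.0, scaffold_peaks))
    spectra, truth = [], {}
    for d in range(n_derivatives):
        sid = f"{family_id}_der{d + 1}"
        scaf_int = rng.uniform(2e4, 1e5, scaffold_peaks)
        uniq_mz = rng.uniform(100.0, base_precursor - 30.0, n_unique_peaks)
        uniq_int = rng.uniform(2e3, 8e3, n_unique_peaks)
        peaks = np.column_stack(
            [np.concatenate([scaffold_mz, uniq_mz]), np.concatenate([scaf_int, uniq_int])]
        )
        spectra.append(
            MsmsSpectrum(
                spectrum_id=sid,
                precursor_mz=base_precursor + d * loss_step,
                peaks=peaks,
            )
        )
        truth[sid] = family_id
    return spectra, truth


def gen_random_spectra(
    n: int = 5,
    n_peaks: int = 12,
    mz_range: tuple[float, float] = (600.0, 1000.0),
    seed: int = 0,
    prefix: str = "bg",
) -> list[MsmsSpectrum]:
    """Unrelated background spectra in a separate fragment m/z region."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        peaks = np.column_stack(
            [
                np.sort(rng.uniform(mz_range[0], mz_range[1], n_peaks)),
                rng.uniform(2e3, 5e4, n_peaks),
            ]
        )
        out.append(
            MsmsSpectrum(
                spectrum_id=f"{prefix}_{i + 1}",
                precursor_mz=float(rng.uniform(mz_range[1], mz_range[1] + 200.0)),
                peaks=peaks,
            )
        )
    return out


def gen_fraction_plate(
    scheme: FractionScheme | None = None,
    spiked_windows: list[tuple[tuple[int, int], float]] | None = None,
    noise_sd: float = 0.02,
    growth_od: float = 1.0,
    medium_od: float = 0.08,
    n_control_wells: int = 8,
    seed: int = 0,
) -> tuple[FractionPlate, dict]:
    """Microfractionation assay plate with spiked activity windows.

    ``spiked_windows`` is a list of ((first, last), percent_inhibition);
    windows must not overlap.  Control wells sit at nominal OD with Gaussian
    noise of standard deviation ``noise_sd`` (relative to the growth OD).
    Returns (plate, truth) where truth lists the planted active fractions.
    """
    scheme = scheme or FractionScheme()
    spiked_windows = spiked_windows or []
    covered: set[int] = set()
    for (lo, hi), _ in spiked_windows:
        if not 1 <= lo <= hi <= scheme.n_fractions:
            raise ValueError(f"window ({lo}, {hi}) outside 1..{scheme.n_fractions}")
        span = set(range(lo, hi + 1))
        if covered & span:
            raise ValueError("overlapping spike windows")
        covered |= span
    rng = np.random.default_rng(seed)
    sd = noise_sd * growth_od

    wells: dict[str, tuple[str, float]] = {}
    layout: dict[str, int] = {}
    for i in range(n_control_wells):
        wells[f"M{i + 1:02d}"] = ("medium-control", max(float(medium_od + rng.normal(0, sd)), 0.0))
        wells[f"G{i + 1:02d}"] = ("growth-control", max(float(growth_od + rng.normal(0, sd)), 0.0))
        wells[f"P{i + 1:02d}"] = ("positive-control", max(float(medium_od + rng.normal(0, sd)), 0.0))
    inhibition_of = {f: lvl for (lo, hi), lvl in spiked_windows for f in range(lo, hi + 1)}
    for f in range(1, scheme.n_fractions + 1):
        inh = inhibition_of.get(f, 0.0)
        nominal = growth_od - inh / 100.0 * (growth_od - medium_od)
        well = f"F{f:03d}"
        wells[well] = ("sample", max(float(nominal + rng.normal(0, sd)), 0.0))
        layout[well] = f
    plate = FractionPlate(wells=wells, layout=layout)
    truth = {"active_fractions": sorted(covered), "windows": [list(w) for w, _ in spiked_windows]}
    return plate, truth


def study_scale() -> dict:
    """Default scenario: a study-scale stated world.

    60 extracts in 8 metabolic groups plus 4 sparse samples (so the 50-feature
    filter trims 64 to 60), a 3-clone x 3-copy fingerprint set, one 7-member
    spectral family with 10 scaffold peaks among 5 unrelated spectra, and a
    159-fraction plate with one active window (fractions 84-87 at 95%
    inhibition, 2% OD noise).
    """
    return {
        "community": {"n_taxa": 60, "total_reads": 100_000, "concentration": 50.0},
        "features": {
            "n_groups": 8,
            "samples_per_group": [20, 10, 8, 7, 5, 4, 3, 3],
            "n_buckets": 200,
            "within_share": 0.95,
            "between_share": 0.05,
            "intensity_cv": 0.1,
            "n_sparse_samples": 4,
        },
        "fingerprints": {"n_clones": 3, "copies_per_clone": 3,
                         "n_registry_bands": 30, "flip_prob": 0.05},
        "spectra": {"scaffold_peaks": 10, "n_derivatives": 7, "n_background": 5},
        "plate": {"spiked_windows": [[[84, 87], 95.0]], "noise_sd": 0.02},
    }


def generate_scenario(out_dir, seed: int, params: dict | None = None) -> dict:
    """Write every pipeline input for a scenario to ``out_dir`` plus truth.json.

    Emits: taxon_table.tsv, features.csv (long format), bands.csv,
    spectra.mgf, plate.csv and truth.json.  Deterministic for a fixed seed.
    Returns the truth dict.
    """
    params = params or study_scale()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, 5)]

    profile, true_h = gen_community(seed=sub[0], **params["community"])
    pd.DataFrame({profile.sample_id: profile.counts}).rename_axis("taxon").to_csv(
        out / "taxon_table.tsv", sep="\t"
    )

    fls, feature_truth = gen_feature_tables(seed=sub[1], **params["features"])
    long = pd.concat(
        [fl.features.assign(sample=fl.sample_id) for fl in fls], ignore_index=True
    )
    long[["sample", "rt_s", "mz", "intensity"]].to_csv(out / "features.csv", index=False)

    bands, clone_truth = gen_fingerprints(seed=sub[2], **params["fingerprints"])
    pd.DataFrame(
        [(s, b) for s, sizes in bands.items() for b in sizes],
        columns=["strain", "band_size_bp"],
    ).to_csv(out / "bands.csv", index=False)

    spectra_params = dict(params["spectra"])
    n_background = spectra_params.pop("n_background", 0)
    family, family_truth = gen_compound_family(seed=sub[3], **spectra_params)
    background = gen_random_spectra(n=n_background, seed=sub[3] + 1)
    write_mgf(family + background, out / "spectra.mgf")

    plate, plate_truth = gen_fraction_plate(
        spiked_windows=[
            ((int(lo), int(hi)), float(lvl)) for (lo, hi), lvl in params["plate"]["spiked_windows"]
        ],
        noise_sd=params["plate"]["noise_sd"],
        seed=sub[4],
    )
    pd.DataFrame(
        [
            {"well": w, "role": role, "fraction": plate.layout.get(w, ""), "readout": r}
            for w, (role, r) in sorted(plate.wells.items())
        ]
    ).to_csv(out / "plate.csv", index=False)

    truth = {
        "seed": seed,
        "community": {"true_shannon": true_h},
        "features": {"groups": feature_truth},
        "fingerprints": {"clones": clone_truth},
        "spectra": {"families": family_truth,
                    "background": [sp.spectrum_id for sp in background]},
        "plate": plate_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
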
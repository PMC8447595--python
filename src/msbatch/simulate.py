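"""Seeded generator of proteomics-like matrices with known batch structure.

The simulator produces the structures that the rest of the package
diagnoses and corrects, each with its ground-truth component stored for
recovery tests:

* per-batch continuous MS signal drift over running order (linear,
  exponential-decay or sinusoid families), scaled per feature by a random
  sensitivity so peptides respond heterogeneously;
* discrete per-feature per-batch shifts;
* protein-grouped peptides sharing a baseline and biological effects;
* constant-amount spike-in peptides (zero biology, zero discrete shift,
  full drift exposure) mimicking iRT standards;
* replicate re-injections of the same biospecimens spread over the run;
* missingness with logistic dependence on abundance and batch.

Additivity is exact: baseline + biology + individual + shift + drift +
noise equals the generated intensity before missingness, bit for bit.  All
randomness flows from one seed through named substreams, so adding a
component never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FeatureAnnotation, SampleAnnotation, wide_to_long

DRIFT_FAMILIES = ("sinusoid", "linear", "exponential_decay")


@dataclass
class SimulationSpec:
    """Conditions of a simulated experiment (log2-scale effect sizes).

    Defaults: 100 proteins x 3 peptides over 90 samples in 3 equal batches,
    drift amplitude 1.0 log2 (peak-to-peak), discrete shift sd 0.5, noise sd
    0.3, two biological groups, two replicate triples, 5 spike-ins,
    no missingness.
    """

    n_proteins: int = 100
    peptides_per_protein: int = 3
    n_samples: int = 90
    n_batches: int = 3
    batch_sizes: tuple | None = None  # default: as equal as possible
    drift_families: tuple = ("exponential_decay", "linear")  # cycled over batches; monotone by default
    drift_amplitude: float = 1.0  # log2, peak-to-peak within a batch
    shift_sd: float = 0.5  # per-feature per-batch discrete shift
    n_groups: int = 2  # biological groups (e.g. diet)
    bio_effect_sd: float = 0.5  # per-protein group effect
    frac_affected: float = 0.3  # fraction of proteins with a group effect
    individual_sd: float = 0.0  # optional per-individual per-protein variation
    noise_sd: float = 0.3
    replicate_plan: tuple = (("REP1", 3), ("REP2", 3))  # (group label, n injections)
    missing_rate: float = 0.0  # overall baseline missingness
    batch_missing_odds: float = 1.0  # odds multiplier in the coupled batch
    batch_missing_feature_frac: float = 0.3  # fraction of features coupled
    coupled_batch: int = -1  # index of the batch with extra missingness
    abundance_missing_slope: float = 0.0  # logit units per log2 below the median
    n_spike_ins: int = 5
    baseline_mean: float = 20.0  # log2 protein baseline
    baseline_sd: float = 1.5
    peptide_jitter_sd: float = 0.7
    sensitivity_range: tuple = (0.3, 1.5)  # per-feature drift sensitivity
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.batch_sizes is None:
            base = self.n_samples // self.n_batches
            extra = self.n_samples % self.n_batches
            self.batch_sizes = tuple(
                base + (1 if i < extra else 0) for i in range(self.n_batches)
            )
        if sum(self.batch_sizes) != self.n_samples:
            raise ValueError("batch_sizes must sum to n_samples")
        n_rep_inj = sum(k for _, k in self.replicate_plan)
        if n_rep_inj > self.n_samples:
            raise ValueError("replicate injections exceed the number of samples")
        for fam in self.drift_families:
            if fam not in DRIFT_FAMILIES:
                raise ValueError(f"unknown drift family '{fam}'")
        if self.n_spike_ins > self.n_proteins:
            raise ValueError("more spike-ins than proteins")


@dataclass
class GroundTruth:
    """Every additive component of the simulation, features x samples."""

    baseline: pd.DataFrame
    bio_effect: pd.DataFrame
    individual: pd.DataFrame
    shift: pd.DataFrame
    drift: pd.DataFrame
    noise: pd.DataFrame
    complete: pd.DataFrame  # intensities before missingness
    missing_mask: pd.DataFrame  # True where dropped
    drift_free: pd.DataFrame  # complete minus drift component
    sample_drift: pd.Series  # the per-sample drift curve d_b(order)
    feature_sensitivity: pd.Series


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent named substream derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _drift_shape(family: str, u: np.ndarray) -> np.ndarray:
    """Unit-amplitude drift shape over within-batch fraction u in [0, 1]."""
    if family == "linear":
        raw = -u
    elif family == "exponential_decay":
        raw = np.exp(-3.0 * u)
    else:  # sinusoid
        raw = np.sin(2.0 * np.pi * u)
    span = raw.max() - raw.min()
    if span == 0:
        return np.zeros_like(raw)
    scaled = raw / span
    # median-zero within the batch: the drift/shift decomposition is only
    # identifiable up to per-batch constants, and constants are the discrete
    # component by convention
    return scaled - np.median(scaled)


def simulate(spec: SimulationSpec):
    """Generate (table, sample annotation, feature annotation, ground truth)."""
    seed = spec.seed

    # --- samples, individuals, replicates, batches ------------------------
    n = spec.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    run_order = np.arange(1, n + 1)
    batch_labels = np.repeat(
        [f"B{i + 1}" for i in range(spec.n_batches)], spec.batch_sizes
    )

    rng_design = _rng(seed, "design")
    n_rep_inj = sum(k for _, k in spec.replicate_plan)
    rep_positions = np.sort(rng_design.choice(n, size=n_rep_inj, replace=False))
    rep_group_of_pos = {}
    flat = [name for name, k in spec.replicate_plan for _ in range(k)]
    shuffled = rng_design.permutation(len(flat))
    for pos, idx in zip(rep_positions, shuffled):
        rep_group_of_pos[int(pos)] = flat[idx]

    # individuals: one per non-replicate sample + one per replicate group
    individual_of_sample = []
    next_ind = 0
    rep_individual = {}
    for i in range(n):
        if i in rep_group_of_pos:
            g = rep_group_of_pos[i]
            if g not in rep_individual:
                rep_individual[g] = f"I{next_ind + 1:03d}"
                next_ind += 1
            individual_of_sample.append(rep_individual[g])
        else:
            individual_of_sample.append(f"I{next_ind + 1:03d}")
            next_ind += 1
    individuals = sorted(set(individual_of_sample))
    group_names = [f"G{i + 1}" for i in range(spec.n_groups)]
    perm = rng_design.permutation(len(individuals))
    group_of_individual = {
        ind: group_names[perm[i] % spec.n_groups] for i, ind in enumerate(individuals)
    }
    group_of_sample = [group_of_individual[i] for i in individual_of_sample]

    ann_frame = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "run_order": run_order,
            "MS_batch": batch_labels,
            "group": group_of_sample,
            "individual": individual_of_sample,
            "replicate_group": [
                rep_group_of_pos.get(i, np.nan) for i in range(n)
            ],
        }
    )
    annotation = SampleAnnotation(
        ann_frame,
        batch_factors=["MS_batch"],
        bio_factors=["group"],
        replicate_group="replicate_group",
    )

    # --- features ---------------------------------------------------------
    proteins = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    rng_spike = _rng(seed, "spike")
    spike_proteins = set(
        rng_spike.choice(spec.n_proteins, size=spec.n_spike_ins, replace=False)
    )
    # spike-in *proteins* (e.g. fetuin-style standards) keep the usual
    # peptide multiplicity; all their peptides carry the spike-in flag
    feature_ids, protein_of_feature, is_spike = [], [], []
    for p_idx, p in enumerate(proteins):
        n_pep = spec.peptides_per_protein
        for j in range(n_pep):
            feature_ids.append(f"{p}_pep{j + 1}")
            protein_of_feature.append(p)
            is_spike.append(p_idx in spike_proteins)
    G = len(feature_ids)
    fann = FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": feature_ids,
                "protein_id": protein_of_feature,
                "is_spike_in": is_spike,
            }
        )
    )
    spike_mask = np.asarray(is_spike)
    prot_index = pd.Series(
        pd.factorize(pd.Index(protein_of_feature))[0], index=feature_ids
    )

    # --- components -------------------------------------------------------
    rng_base = _rng(seed, "baseline")
    protein_baseline = rng_base.normal(spec.baseline_mean, spec.baseline_sd, spec.n_proteins)
    pep_jitter = rng_base.normal(0.0, spec.peptide_jitter_sd, G)
    baseline = protein_baseline[prot_index.to_numpy()] + pep_jitter

    rng_bio = _rng(seed, "bioeffect")
    affected = rng_bio.random(spec.n_proteins) < spec.frac_affected
    protein_effect = np.zeros((spec.n_proteins, spec.n_groups))
    protein_effect[:, 1:] = rng_bio.normal(
        0.0, spec.bio_effect_sd, size=(spec.n_proteins, spec.n_groups - 1)
    )
    protein_effect[~affected] = 0.0
    group_idx = np.asarray([group_names.index(g) for g in group_of_sample])
    bio = protein_effect[prot_index.to_numpy()][:, group_idx]
    bio[spike_mask] = 0.0

    rng_ind = _rng(seed, "individual")
    ind_effect = rng_ind.normal(
        0.0, spec.individual_sd, size=(spec.n_proteins, len(individuals))
    )
    ind_idx = np.asarray([individuals.index(i) for i in individual_of_sample])
    individual = ind_effect[prot_index.to_numpy()][:, ind_idx]
    individual[spike_mask] = 0.0

    rng_shift = _rng(seed, "shift")
    shift_gb = rng_shift.normal(0.0, spec.shift_sd, size=(G, spec.n_batches))
    shift_gb[spike_mask] = 0.0
    batch_idx = np.repeat(np.arange(spec.n_batches), spec.batch_sizes)
    shift = shift_gb[:, batch_idx]

    rng_sens = _rng(seed, "sensitivity")
    sens = rng_sens.uniform(*spec.sensitivity_range, size=G)
    sample_drift = np.zeros(n)
    start = 0
    for b, size in enumerate(spec.batch_sizes):
        fam = spec.drift_families[b % len(spec.drift_families)]
        u = (np.arange(size) + 0.5) / size
        sample_drift[start : start + size] = spec.drift_amplitude * _drift_shape(fam, u)
        start += size
    drift = sens[:, None] * sample_drift[None, :]

    rng_noise = _rng(seed, "noise")
    noise = rng_noise.normal(0.0, spec.noise_sd, size=(G, n))

    complete = baseline[:, None] + bio + individual + shift + drift + noise

    # --- missingness (applied last) ---------------------------------------
    rng_miss = _rng(seed, "missingness")
    if spec.missing_rate > 0:
        base_logit = np.log(spec.missing_rate / (1.0 - spec.missing_rate))
        med = np.median(complete)
        logit = (
            base_logit
            + spec.abundance_missing_slope * (med - complete)
        )
        # batch coupling is feature-blocked: an affected peptide misses at
        # elevated odds throughout the coupled batch (whole-batch dropout is
        # what turns zero-filling into spurious batch clusters)
        coupled = spec.coupled_batch % spec.n_batches
        affected = rng_miss.random(G) < spec.batch_missing_feature_frac
        logit[np.ix_(affected, batch_idx == coupled)] += np.log(spec.batch_missing_odds)
        p_miss = 1.0 / (1.0 + np.exp(-logit))
        mask = rng_miss.random(size=(G, n)) < p_miss
    else:
        mask = np.zeros((G, n), dtype=bool)

    def frame(arr):
        return pd.DataFrame(arr, index=feature_ids, columns=sample_ids)

    observed = complete.copy()
    observed[mask] = np.nan
    wide_obs = frame(observed)
    wide_obs.index.name = "feature_id"
    wide_obs.columns.name = "sample_id"
    table = wide_to_long(wide_obs)

    truth = GroundTruth(
        baseline=frame(np.broadcast_to(baseline[:, None], (G, n)).copy()),
        bio_effect=frame(bio),
        individual=frame(individual),
        shift=frame(shift),
        drift=frame(drift),
        noise=frame(noise),
        complete=frame(complete),
        missing_mask=frame(mask),
        drift_free=frame(complete - drift),
        sample_drift=pd.Series(sample_drift, index=sample_ids),
        feature_sensitivity=pd.Series(sens, index=feature_ids),
    )
    return table, annotation, fann, truth


def worked_fixture():
    """Tiny hand-checkable dataset: 6 proteins x 2 peptides, 12 samples,
    2 batches of 6, 2 replicate pairs, a +1 log2 shift on batch 2 for
    odd-numbered proteins, no drift, no noise.

    The values are literals chosen so that medians, shifts and correlations
    can be verified by hand; every table validates against the package's
    type invariants.
    """
    sample_ids = [f"S{i:02d}" for i in range(1, 13)]
    ann = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "run_order": range(1, 13),
                "MS_batch": ["B1"] * 6 + ["B2"] * 6,
                "group": ["G1", "G2"] * 6,
                "replicate_group": [
                    "REP1", np.nan, np.nan, np.nan, np.nan, np.nan,
                    "REP1", np.nan, "REP2", np.nan, np.nan, "REP2",
                ],
            }
        ),
        batch_factors=["MS_batch"],
        bio_factors=["group"],
        replicate_group="replicate_group",
    )
    proteins = [f"P{i}" for i in range(1, 7)]
    feature_ids = [f"{p}_pep{j}" for p in proteins for j in (1, 2)]
    fann = FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": feature_ids,
                "protein_id": [p for p in proteins for _ in (1, 2)],
                "is_spike_in": [p == "P6" for p in proteins for _ in (1, 2)],
            }
        )
    )
    # base level 10 + protein index; per-sample biological wiggle 0.1*k for
    # sample k within protein; +1 shift in batch 2 for odd proteins
    values = {}
    for gi, feat in enumerate(feature_ids):
        p_idx = gi // 2  # protein number - 1
        base = 10.0 + p_idx
        row = []
        for k in range(12):
            shift = 1.0 if (k >= 6 and p_idx % 2 == 0) else 0.0  # P1, P3, P5
            row.append(base + 0.1 * k + shift)
        values[feat] = row
    wide = pd.DataFrame(values, index=sample_ids).T
    wide.index.name = "feature_id"
    wide.columns.name = "sample_id"
    table = wide_to_long(wide)
    return table, ann, fann
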
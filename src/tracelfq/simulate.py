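"""Synthetic ion tables with known ground truth.

Emulates mixed-species spike-in designs: a background species present at
constant amount across two conditions plus spiked species whose amounts
differ by a known linear ratio.  Each ion's log2 intensity is

    base + ionization offset + condition effect + loading offset + noise

with the condition effect (log2 of the species fold change, convention
condition1 - condition2) applied to condition-1 samples, additive Gaussian
noise in log2 space (multiplicative log-normal in linear space, the
standard model for MS intensity error) and intensity-dependent missingness:
a record is dropped with a probability that follows a logistic curve in its
log2 intensity, calibrated so the marginal missing fraction matches the
configured value — low-abundance ions go missing more often, as in real
left-censored MS data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .ion_table import IonTable, make_ion_id


@dataclass
class SimulationConfig:
    """Study design of a simulated two-condition spike-in experiment.

    ``species_fold_changes`` maps species name -> linear abundance ratio
    condition1/condition2; ``n_proteins`` maps species name -> protein
    count.  ``ions_per_protein`` is an inclusive (low, high) range of
    precursors per protein.  ``fragments_per_precursor`` > 0 emulates DIA:
    each precursor contributes one MS1 trace plus that many fragment-ion
    traces, each with its own ionization offset; 0 emulates DDA (MS1 only).
    ``sample_loading_offsets`` (log2) defaults to zeros.
    """

    n_proteins: dict = field(default_factory=lambda: {"background": 400,
                                                      "spike": 200})
    species_fold_changes: dict = field(default_factory=lambda: {
        "background": 1.0, "spike": 6.0})
    n_samples_per_condition: int = 3
    ions_per_protein: tuple = (2, 6)
    fragments_per_precursor: int = 0
    base_log2_intensity: tuple = (18.0, 30.0)
    ionization_offset_sd: float = 2.0
    noise_sd: float = 0.3
    sample_loading_offsets: list | None = None
    missing_fraction: float = 0.15
    missingness_steepness: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if set(self.n_proteins) != set(self.species_fold_changes):
            problems.append("n_proteins and species_fold_changes must list "
                            "the same species")
        if any(n < 1 for n in self.n_proteins.values()):
            problems.append("n_proteins: all counts must be >= 1")
        if any(fc <= 0 for fc in self.species_fold_changes.values()):
            problems.append("species_fold_changes: all ratios must be > 0")
        if self.n_samples_per_condition < 1:
            problems.append("n_samples_per_condition must be >= 1")
        lo, hi = self.ions_per_protein
        if not (1 <= lo <= hi):
            problems.append("ions_per_protein must satisfy 1 <= low <= high")
        if self.fragments_per_precursor < 0:
            problems.append("fragments_per_precursor must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            problems.append("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.ionization_offset_sd < 0:
            problems.append("noise_sd and ionization_offset_sd must be >= 0")
        if self.sample_loading_offsets is not None and (
                len(self.sample_loading_offsets)
                != 2 * self.n_samples_per_condition):
            problems.append("sample_loading_offsets must have one entry per "
                            "sample (2 * n_samples_per_condition)")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Per-protein, per-sample and per-ion true parameters of a simulation."""

    protein_truth: pd.DataFrame   # protein, species, true_log2_fc
    sample_truth: pd.DataFrame    # sample, condition, loading_offset
    ion_truth: pd.DataFrame       # ion, protein, ionization_offset, base_log2


def _calibrated_missing_probs(log2_int: np.ndarray, fraction: float,
                              steepness: float) -> np.ndarray:
    """Logistic missingness probabilities with the requested marginal rate.

    Solves for the midpoint x0 of p(x) = sigmoid(-steepness * (x - x0))
    such that mean(p) equals ``fraction``.
    """
    if fraction == 0:
        return np.zeros_like(log2_int)

    def marginal(x0):
        return expit(-steepness * (log2_int - x0)).mean() - fraction

    lo, hi = log2_int.min() - 60, log2_int.max() + 60
    x0 = brentq(marginal, lo, hi)
    return expit(-steepness * (log2_int - x0))


def simulate_dataset(cfg: SimulationConfig) -> tuple:
    """Generate an :class:`IonTable` and its :class:`GroundTruth`.

    Fully deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_cond = cfg.n_samples_per_condition
    samples = [f"S1_rep{i+1}" for i in range(n_cond)] + \
              [f"S2_rep{i+1}" for i in range(n_cond)]
    conditions = np.array([1] * n_cond + [2] * n_cond)
    if cfg.sample_loading_offsets is None:
        loading = np.zeros(2 * n_cond)
    else:
        loading = np.asarray(cfg.sample_loading_offsets, dtype=float)

    prot_rows, ion_rows = [], []
    records_protein, records_ion, records_log2 = [], [], []
    sample_col, intensity_col = [], []

    for species in sorted(cfg.n_proteins):
        fc_log2 = float(np.log2(cfg.species_fold_changes[species]))
        for p in range(cfg.n_proteins[species]):
            protein = f"{species}_P{p:04d}"
            prot_rows.append((protein, species, fc_log2))
            base = rng.uniform(*cfg.base_log2_intensity)
            n_prec = int(rng.integers(cfg.ions_per_protein[0],
                                      cfg.ions_per_protein[1] + 1))
            for q in range(n_prec):
                tags = ["MS1"] + [f"FRG{k}" for k in
                                  range(cfg.fragments_per_precursor)]
                for tag in tags:
                    ion = make_ion_id(f"{protein}_SEQ{q}", 2, tag)
                    off = rng.normal(0.0, cfg.ionization_offset_sd)
                    ion_rows.append((ion, protein, off, base))
                    cond_eff = np.where(conditions == 1, fc_log2, 0.0)
                    noise = rng.normal(0.0, cfg.noise_sd, size=len(samples))
                    log2_int = base + off + cond_eff + loading + noise
                    records_protein.extend([protein] * len(samples))
                    records_ion.extend([ion] * len(samples))
                    sample_col.extend(samples)
                    records_log2.append(log2_int)

    log2_all = np.concatenate(records_log2)
    intensity_col = np.exp2(log2_all)
    df = pd.DataFrame({
        "protein": records_protein,
        "ion": records_ion,
        "sample": sample_col,
        "intensity": intensity_col,
    })
    if cfg.missing_fraction > 0:
        p_miss = _calibrated_missing_probs(
            log2_all, cfg.missing_fraction, cfg.missingness_steepness)
        keep = rng.random(len(df)) >= p_miss
        df = df[keep]

    truth = GroundTruth(
        protein_truth=pd.DataFrame(
            prot_rows, columns=["protein", "species", "true_log2_fc"]),
        sample_truth=pd.DataFrame(
            {"sample": samples, "condition": conditions,
             "loading_offset": loading}),
        ion_truth=pd.DataFrame(
            ion_rows, columns=["ion", "protein", "ionization_offset",
                               "base_log2"]),
    )
    return IonTable(df, validate=False), truth


def dda_spikein_config(seed: int = 0) -> SimulationConfig:
    """Standard DDA mixed-species benchmark design.

    400 constant background proteins plus 200 proteins of a spiked species
    present at 6-fold higher amount in condition 1 (3 vs 3 samples), 2-6
    MS1 precursor ions per protein, 0.3 log2 multiplicative noise and 15%
    intensity-dependent missingness.  The expected per-protein log2 fold
    change (low minus high condition) is -log2(6) = -2.585 for the spiked
    species and 0 for the background.
    """
    return SimulationConfig(
        n_proteins={"background": 400, "spike": 200},
        species_fold_changes={"background": 1.0, "spike": 6.0},
        n_samples_per_condition=3,
        ions_per_protein=(2, 6),
        fragments_per_precursor=0,
        noise_sd=0.3,
        missing_fraction=0.15,
        seed=seed,
    )


def dia_threespecies_config(seed: int = 0) -> SimulationConfig:
    """Standard DIA three-species benchmark design.

    Three species blocks of 200 proteins at condition1:condition2 linear
    ratios 0.77, 1 and 2 (expected log2 fold changes -0.38, 0 and 1), 3 vs
    3 samples, 2-4 precursors per protein each contributing one MS1 trace
    plus three fragment-ion traces.
    """
    return SimulationConfig(
        n_proteins={"celegans_like": 200, "human_like": 200,
                    "yeast_like": 200},
        species_fold_changes={"celegans_like": 0.77, "human_like": 1.0,
                              "yeast_like": 2.0},
        n_samples_per_condition=3,
        ions_per_protein=(2, 4),
        fragments_per_precursor=3,
        noise_sd=0.3,
        missing_fraction=0.15,
        seed=seed,
    )


def simulate_tissue_dataset(seed: int = 0, n_proteins: int = 500,
                            ions_per_protein: int = 3,
                            samples_per_tissue: int = 2,
                            noise_sd: float = 0.15,
                            missing_fraction: float = 0.3,
                            missingness_steepness: float = 1.2):
    """Tissue-like dataset with block-regulated proteins and censoring.

    Emulates the normalization stress of comparing proteomes with strongly
    different compositions: three tissues, each pair of tissues separated
    by large blocks of up- and down-regulated proteins (tissue B: 15% up
    +2 / 15% down -2 log2 relative to tissue A; tissue C: 25% up +3 / 25%
    down -3), plus per-sample loading offsets and heavy left-censored
    missingness.  Because censoring removes down-regulated ions
    preferentially, the observed per-sample intensity median is biased in
    a tissue-dependent way — the failure mode of naive per-sample median
    normalization, which pairwise-median trace shifting is robust to.

    Returns ``(IonTable, sample_truth)`` where sample_truth lists each
    sample's tissue and loading offset.
    """
    rng = np.random.default_rng(seed)
    tissues = ["A", "B", "C"]
    samples = [f"{t}_rep{r+1}" for t in tissues
               for r in range(samples_per_tissue)]
    tissue_of = np.repeat(tissues, samples_per_tissue)
    loading = rng.uniform(-0.5, 0.5, size=len(samples))

    # per-protein regulation block (log2 effect per tissue, A = reference)
    effects = np.zeros((n_proteins, len(tissues)))
    u = rng.random(n_proteins)
    effects[u < 0.15, 1] = 2.0
    effects[(u >= 0.15) & (u < 0.30), 1] = -2.0
    v = rng.random(n_proteins)
    effects[v < 0.25, 2] = 3.0
    effects[(v >= 0.25) & (v < 0.50), 2] = -3.0

    tissue_idx = {t: k for k, t in enumerate(tissues)}
    sample_effect_col = np.array([tissue_idx[t] for t in tissue_of])

    rows_protein, rows_ion, rows_sample, log2_vals = [], [], [], []
    for p in range(n_proteins):
        protein = f"T_P{p:04d}"
        base = rng.uniform(18.0, 30.0)
        for q in range(ions_per_protein):
            ion = make_ion_id(f"{protein}_SEQ{q}", 2, "MS1")
            off = rng.normal(0.0, 2.0)
            noise = rng.normal(0.0, noise_sd, size=len(samples))
            vals = base + off + effects[p, sample_effect_col] + loading + noise
            rows_protein.extend([protein] * len(samples))
            rows_ion.extend([ion] * len(samples))
            rows_sample.extend(samples)
            log2_vals.append(vals)

    log2_all = np.concatenate(log2_vals)
    df = pd.DataFrame({"protein": rows_protein, "ion": rows_ion,
                       "sample": rows_sample,
                       "intensity": np.exp2(log2_all)})
    p_miss = _calibrated_missing_probs(log2_all, missing_fraction,
                                       missingness_steepness)
    df = df[rng.random(len(df)) >= p_miss]
    sample_truth = pd.DataFrame({"sample": samples, "tissue": tissue_of,
                                 "loading_offset": loading})
    return IonTable(df, validate=False), sample_truth


def end_to_end_truth_recovery(cfg: SimulationConfig) -> dict:
    """Run the full pipeline on a simulated table and score it.

    Returns per-species bias and SD of the estimated log2 fold changes
    (condition 1 minus condition 2) against truth, and the maximum absolute
    error of the recovered per-sample loading factors (both median-centered
    to remove the arbitrary global gauge).
    """
    from .evaluation import log2fc_per_protein
    from .normalization import normalize_samples
    from .quant import quantify_all_proteins

    table, truth = simulate_dataset(cfg)
    norm = normalize_samples(table)
    result = quantify_all_proteins(norm.normalized_table)

    st = truth.sample_truth
    g1 = list(st.loc[st["condition"] == 1, "sample"])
    g2 = list(st.loc[st["condition"] == 2, "sample"])
    fc = log2fc_per_protein(result.intensities, g1, g2)

    merged = truth.protein_truth.set_index("protein").join(fc.rename("est"))
    report = {"species": {}}
    for species, sub in merged.groupby("species"):
        err = (sub["est"] - sub["true_log2_fc"]).dropna()
        report["species"][species] = {
            "median_log2_fc": float(sub["est"].median()),
            "bias": float(err.mean()),
            "sd": float(err.std(ddof=1)) if len(err) > 1 else 0.0,
            "n": int(sub["est"].notna().sum()),
        }
    true_load = st.set_index("sample")["loading_offset"]
    true_load = true_load - true_load.median()
    # normalization must cancel the loading offsets: factor ~ -offset
    resid = (norm.log2_factors + true_load).abs()
    report["max_loading_factor_error"] = float(resid.max())
    return report
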
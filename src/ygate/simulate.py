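"""Sex-structured synthetic microarray data with planted ground truth.

The generator emulates an RMA-normalized log2 expression matrix: a unimodal
Gaussian background-noise component shared by both sexes, Y-chromosome
probes that are elevated only in male samples (the signal the thresholding
procedure exploits), and planted expressed probes at low/medium/high levels.
Normal noise on the log2 scale is used throughout, matching the approximate
per-probe Gaussianity of RMA output that the z-based threshold relies on.

What this does *not* emulate: probe-specific affinity ("probe effect")
beyond per-probe mean offsets, raw CEL intensities, and correlated
expression between probes. Seeds are required arguments, never global
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ygate.io import GeneSet

__all__ = ["SimulationConfig", "SyntheticTruth", "generate", "make_paper_fixture", "PaperFixture"]

#: the three level bins a planted expressed probe can occupy
_LEVELS = ("low", "medium", "high")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror a 16-sample leukocyte study design: nine males and
    seven females, 124 Y-chromosome probes of which four are genuinely
    male-specific, and a log2 background centred near 2.8 (typical RMA
    floor). ``male_effect`` is the log2 shift added to male samples on the
    Y-specific probes; planted expressed probes sit at the centres of the
    low/medium/high level bins.
    """

    seed: int
    n_male: int = 9
    n_female: int = 7
    n_probes: int = 500
    n_y_specific: int = 4
    n_y_neutral: int = 120
    bg_mean: float = 2.8
    bg_sd: float = 0.5
    male_effect: float = 6.0
    n_low: int = 20
    n_medium: int = 20
    n_high: int = 20
    low_mean: float = 5.0
    medium_mean: float = 8.0
    high_mean: float = 12.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        counts = (
            self.n_male, self.n_female, self.n_probes, self.n_y_specific,
            self.n_y_neutral, self.n_low, self.n_medium, self.n_high,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.male_effect < 0:
            raise ValueError("male_effect must be >= 0")
        if not self.low_mean < self.medium_mean < self.high_mean:
            raise ValueError("level means must be ordered low < medium < high")
        planted = (
            self.n_y_specific + self.n_y_neutral
            + self.n_low + self.n_medium + self.n_high
        )
        if planted > self.n_probes:
            raise ValueError(
                f"{planted} structured probes exceed n_probes={self.n_probes}"
            )
        if self.n_y_specific > 0 and (self.n_male == 0 or self.n_female == 0):
            raise ValueError(
                "Y-specific probes require at least one sample of each sex"
            )


#: alias documenting the truth table's role; columns: chromosome,
#: is_y_specific, status in {background, low, medium, high}
SyntheticTruth = pd.DataFrame


def generate(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SyntheticTruth]:
    """Draw one dataset: (matrix, sample metadata, annotation, truth).

    Background probes are Normal(bg_mean, bg_sd) in every sample;
    Y-specific probes add ``male_effect`` in males only; planted expressed
    probes are Normal(level_mean, noise_sd) in every sample. Fully
    reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"M{i+1}" for i in range(config.n_male)] + [
        f"F{i+1}" for i in range(config.n_female)
    ]
    meta = pd.Series(
        ["male"] * config.n_male + ["female"] * config.n_female,
        index=pd.Index(samples, name="sample_id"),
        name="sex",
    )

    plan: list[tuple[str, str, str, str]] = []  # probe, gene, chrom, status
    for i in range(config.n_y_specific):
        plan.append((f"YS{i+1:04d}", f"YSPEC{i+1}", "Y", "y_specific"))
    for i in range(config.n_y_neutral):
        plan.append((f"YN{i+1:04d}", f"YNEUT{i+1}", "Y", "background"))
    for level, count in zip(_LEVELS, (config.n_low, config.n_medium, config.n_high)):
        for i in range(count):
            plan.append(
                (f"{level[0].upper()}{i+1:04d}", f"{level.upper()}{i+1}", "1", level)
            )
    n_filler = config.n_probes - len(plan)
    for i in range(n_filler):
        plan.append((f"BG{i+1:05d}", f"BGGENE{i+1}", "1", "background"))

    level_means = {
        "low": config.low_mean,
        "medium": config.medium_mean,
        "high": config.high_mean,
    }
    n_samples = len(samples)
    male_mask = np.array([meta[s] == "male" for s in samples])
    values = np.empty((len(plan), n_samples))
    for row, (_, _, _, status) in enumerate(plan):
        if status in level_means:
            values[row] = rng.normal(level_means[status], config.noise_sd, n_samples)
        else:
            values[row] = rng.normal(config.bg_mean, config.bg_sd, n_samples)
            if status == "y_specific":
                values[row, male_mask] += config.male_effect

    probes = [p for p, _, _, _ in plan]
    matrix = pd.DataFrame(
        values, index=pd.Index(probes, name="probe_id"), columns=samples
    )
    annot = pd.DataFrame(
        {
            "gene_symbol": [g for _, g, _, _ in plan],
            "chromosome": [c for _, _, c, _ in plan],
        },
        index=pd.Index(probes, name="probe_id"),
    )
    truth = pd.DataFrame(
        {
            "chromosome": annot["chromosome"],
            "is_y_specific": [s == "y_specific" for _, _, _, s in plan],
            "status": [
                "background" if s == "y_specific" else s for _, _, _, s in plan
            ],
        },
        index=annot.index,
    )
    return matrix, meta, annot, truth


# ---------------------------------------------------------------------------
# Constructed worked example
# ---------------------------------------------------------------------------

#: fixed seed of the bundled fixture (a constructed dataset, not a draw to
#: be varied)
_FIXTURE_SEED = 424_242

#: probe ids of the male-specific Y probes in the bundled fixture
FIXTURE_SELECTED_PROBES = ("8176624", "8176698", "8176709", "8176719")
FIXTURE_SELECTED_GENES = ("DDX3Y", "EIF1AY", "TXLNG2P")

_HOUSEKEEPING = {
    # gene: level mean (log2 fluorescence); all sit above the threshold
    "GAPDH": 12.0, "ACTB": 11.6,
    "B2M": 8.4, "PPIA": 8.0, "RPL13A": 7.6, "UBC": 7.2,
    "PGK1": 5.6, "HPRT1": 5.3, "TBP": 5.0, "GUSB": 4.8, "TFRC": 4.6,
}

_VALIDATION_GENES = {
    # ten genes spanning the dynamic range, as a qPCR validation panel:
    # two per stratum: high, medium, low (expressed), near-threshold and
    # floor (non-expressed)
    "VHIGH1": 11.5, "VHIGH2": 11.0,
    "VMED1": 8.2, "VMED2": 7.8,
    "VLOW1": 5.2, "VLOW2": 4.8,
    "VNEAR1": 3.6, "VNEAR2": 3.4,
    "VBG1": 2.6, "VBG2": 2.4,
}

# Ct = _QPCR_INTERCEPT + _QPCR_SLOPE * Fi + Normal(0, _QPCR_NOISE_SD):
# ~1.5 cycles per log2 fluorescence unit with ~2 cycles of cross-platform
# dispersion, a typical array-vs-qPCR concordance regime.
_QPCR_INTERCEPT = 34.0
_QPCR_SLOPE = -1.5
_QPCR_NOISE_SD = 2.0


@dataclass
class PaperFixture:
    """A bundled 16-sample synthetic dataset shaped like the study design.

    Synthetic throughout — constructed so that its ground truth mirrors the
    qualitative structure of a real leukocyte cohort: 124 Y-chromosome
    probes of which exactly four (three genes) are male-specific and
    non-overlapping, 23 Y genes sex-significant in total, eleven
    housekeeping genes above threshold in every sample, an SRY-like probe
    below threshold everywhere, and a 13-gene qPCR panel. The pooled female
    fluorescence of the four male-specific probes is rescaled so the
    one-sided 95% upper limit equals 4.0 exactly.
    """

    matrix: pd.DataFrame
    meta: pd.Series
    annot: pd.DataFrame
    truth: pd.DataFrame
    qpcr: pd.DataFrame
    qpcr_genes: tuple[str, ...]
    gene_sets: dict[str, GeneSet]


def _interleaved(rng: np.random.Generator, n_m: int, n_f: int, mean: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw n_m + n_f values and deal them to the sexes in alternating rank
    order, so the Mann-Whitney U sits near its null mean by construction."""
    values = np.sort(rng.normal(mean, sd, n_m + n_f))[::-1]
    male, female = [], []
    for i, v in enumerate(values):
        if (i % 2 == 0 and len(male) < n_m) or len(female) >= n_f:
            male.append(v)
        else:
            female.append(v)
    return np.array(male), np.array(female)


def make_paper_fixture() -> PaperFixture:
    """Build the bundled synthetic worked-example dataset (deterministic)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    n_m, n_f = 9, 7
    samples = [f"M{i+1}" for i in range(n_m)] + [f"F{i+1}" for i in range(n_f)]
    meta = pd.Series(
        ["male"] * n_m + ["female"] * n_f,
        index=pd.Index(samples, name="sample_id"),
        name="sex",
    )

    rows: dict[str, np.ndarray] = {}
    annot_rows: list[tuple[str, str, str]] = []
    truth_rows: list[tuple[str, str, bool, str]] = []

    def add(probe: str, gene: str, chrom: str, male: np.ndarray, female: np.ndarray, status: str, y_specific: bool = False) -> None:
        rows[probe] = np.concatenate([male, female])
        annot_rows.append((probe, gene, chrom))
        truth_rows.append((probe, chrom, y_specific, status))

    # --- the four male-specific Y probes (three genes) -------------------
    probe_genes = [
        ("8176624", "DDX3Y"),
        ("8176719", "EIF1AY"),
        ("8176709", "TXLNG2P"),
        ("8176698", "TXLNG2P"),
    ]
    female_draws = [rng.normal(2.85, 0.7, n_f) for _ in probe_genes]
    pooled = np.concatenate(female_draws)
    # rescale the pooled female vector so mean + 1.6449*sd == 4.0 exactly
    target_mean = 2.85
    target_sd = (4.0 - target_mean) / 1.6448536269514722
    pooled = (pooled - pooled.mean()) / pooled.std(ddof=1)
    pooled = pooled * target_sd + target_mean
    female_max = pooled.max()
    for i, (probe, gene) in enumerate(probe_genes):
        female = pooled[i * n_f : (i + 1) * n_f]
        male = female_max + 1.0 + np.abs(rng.normal(0.0, 0.5, n_m)) + 2.0
        add(probe, gene, "Y", male, female, "background", y_specific=True)

    # --- 20 sex-significant but range-overlapping Y genes ----------------
    for i in range(20):
        female = np.sort(rng.normal(3.0, 0.4, n_f))
        male = female.max() + 0.1 + np.abs(rng.normal(0.0, 0.4, n_m))
        male[-1] = np.median(female) - 0.01  # one male inside the female range
        add(f"821{i:04d}", f"YSIG{i+1}", "Y", male, female, "background")

    # --- SRY-like negative control: below threshold in every sample ------
    male, female = _interleaved(rng, n_m, n_f, 2.3, 0.25)
    add("8177231", "SRY", "Y", np.minimum(male, 3.4), np.minimum(female, 3.4), "background")

    # --- 99 sex-neutral Y genes ------------------------------------------
    for i in range(99):
        male, female = _interleaved(rng, n_m, n_f, 2.8, 0.5)
        add(f"820{i:04d}", f"YNEUT{i+1}", "Y", male, female, "background")

    # --- 11 housekeeping genes, always expressed -------------------------
    for i, (gene, level) in enumerate(_HOUSEKEEPING.items()):
        male, female = _interleaved(rng, n_m, n_f, level, 0.3)
        male, female = np.maximum(male, 4.1), np.maximum(female, 4.1)
        status = "high" if level > 10 else ("medium" if level >= 6 else "low")
        add(f"790{i:04d}", gene, "12", male, female, status)

    # --- 10-gene qPCR validation panel -----------------------------------
    for i, (gene, level) in enumerate(_VALIDATION_GENES.items()):
        male, female = _interleaved(rng, n_m, n_f, level, 0.25)
        if level > 10:
            status = "high"
        elif level >= 6:
            status = "medium"
        elif level >= 4:
            status = "low"
        else:
            status = "background"
        add(f"780{i:04d}", gene, "10", male, female, status)

    # --- autosomal background filler --------------------------------------
    for i in range(355):
        male, female = _interleaved(rng, n_m, n_f, 2.8, 0.5)
        add(f"770{i:04d}", f"BGGENE{i+1}", "1", male, female, "background")

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    matrix.index.name = "probe_id"
    annot = pd.DataFrame(
        [(g, c) for _, g, c in annot_rows],
        index=pd.Index([p for p, _, _ in annot_rows], name="probe_id"),
        columns=["gene_symbol", "chromosome"],
    )
    truth = pd.DataFrame(
        [(c, y, s) for _, c, y, s in truth_rows],
        index=annot.index,
        columns=["chromosome", "is_y_specific", "status"],
    )

    # qPCR panel: the ten validation genes plus the three threshold genes
    qpcr_genes = tuple(_VALIDATION_GENES) + FIXTURE_SELECTED_GENES
    qpcr_rows = []
    for gene in qpcr_genes:
        probes = annot.index[annot["gene_symbol"] == gene]
        fi = matrix.loc[probes].mean(axis=0)
        for sample in samples:
            ct = (
                _QPCR_INTERCEPT
                + _QPCR_SLOPE * fi[sample]
                + rng.normal(0.0, _QPCR_NOISE_SD)
            )
            qpcr_rows.append((gene, sample, max(ct, 1.0)))
    qpcr = pd.DataFrame(qpcr_rows, columns=["gene_symbol", "sample_id", "ct"])

    expressed_genes = tuple(
        g for g, lvl in {**_HOUSEKEEPING, **_VALIDATION_GENES}.items() if lvl >= 6
    )
    gene_sets = {
        "HIGH_EXPRESSION_MODULE": GeneSet(
            "genes planted at medium/high expression", expressed_genes
        ),
        "BACKGROUND_DECOYS": GeneSet(
            "background filler genes (should never enrich)",
            tuple(f"BGGENE{i+1}" for i in range(40)),
        ),
    }
    return PaperFixture(
        matrix=matrix,
        meta=meta,
        annot=annot,
        truth=truth,
        qpcr=qpcr,
        qpcr_genes=qpcr_genes,
        gene_sets=gene_sets,
    )
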
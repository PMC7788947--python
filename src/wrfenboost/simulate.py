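"""Seeded generator of synthetic perturbation-signature / viability experiments.

The generator emulates the joint structure of an L1000-style perturbation
screen matched to a cell-viability portal: a matrix of per-instance
differential-expression values over 978 landmark genes, per-instance
metadata (cell line, perturbagen, dose in µM, perturbation time in hours,
replicate batch), a viability table keyed by (cell line, perturbagen, dose,
batch), and a drug-sensitivity table with GI50-style and active-area
columns.

A small planted subset of genes drives viability through a bounded
saturating link.  For compound-like perturbagens the phenotype lives on a
[0, 1] viability scale around a baseline of 0.5; for shRNA-like
perturbagens it is a signed log-fold effect score centred at 0.  The closed
form is::

    viability_i = baseline
                  + amplitude * tanh( w . x_i[informative] / sqrt(m) )
                  + dose_effect * log10(dose_i)        (compound mode only)
                  + Normal(0, noise_sd)

where ``m`` is the number of informative genes and ``w`` their planted
weights.  Replicates of the same (cell line, drug, dose) condition share a
latent informative-gene state, so batch replicates are correlated the way
biological replicates are, while every gene stays standard normal
marginally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: metadata columns of a signature table, in canonical order; every column
#: after these is a gene (or an appended non-gene predictor).
META_COLS = ["instance_id", "cell_line", "pert_id", "pert_type", "dose_um", "time_h", "batch"]

COMPOUND_BASELINE = 0.5
COMPOUND_AMPLITUDE = 0.35
SHRNA_BASELINE = 0.0
SHRNA_AMPLITUDE = 1.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic screen.

    Defaults describe the benchmark condition used throughout the test
    suite: 600 instances over 978 landmark genes, 15 informative genes,
    duplicate batches, mild measurement noise and a weak negative dose
    effect on viability.
    """

    n_instances: int = 600
    n_genes: int = 978
    n_informative: int = 15
    cell_lines: int = 6
    drugs: int = 25
    dose_grid: tuple = (0.12, 0.37, 1.11, 3.33, 10.0)
    times: tuple = (3.0, 6.0, 24.0)
    replicate_batches: int = 2
    noise_sd: float = 0.05
    dose_effect: float = -0.04
    pert_type: str = "compound"  # "compound" | "shRNA"
    replicate_rho: float = 0.7  # within-condition correlation of informative genes
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if any(d <= 0 for d in self.dose_grid):
            raise ValueError("all doses must be positive")
        if self.replicate_batches < 1:
            raise ValueError("replicate_batches must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.pert_type not in ("compound", "shRNA"):
            raise ValueError(f"unknown pert_type {self.pert_type!r}")
        if not 0.0 <= self.replicate_rho < 1.0:
            raise ValueError("replicate_rho must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of a generator run: the planted gene→viability link."""

    informative_genes: list
    weights: dict  # gene id -> planted weight
    baseline: float
    amplitude: float
    dose_effect: float
    pert_type: str
    viability_clean: np.ndarray  # per instance, before noise
    viability: np.ndarray  # per instance, with noise
    instance_ids: list = field(default_factory=list)

    def link(self, signatures: pd.DataFrame) -> np.ndarray:
        """Closed-form noise-free viability for rows of a signature table."""
        m = len(self.informative_genes)
        if m:
            x = signatures[self.informative_genes].to_numpy(float)
            w = np.array([self.weights[g] for g in self.informative_genes])
            score = np.tanh(x @ w / math.sqrt(m))
        else:
            score = np.zeros(len(signatures))
        v = self.baseline + self.amplitude * score
        if self.pert_type == "compound" and self.dose_effect != 0.0:
            v = v + self.dose_effect * np.log10(signatures["dose_um"].to_numpy(float))
        return v


def gene_names(n_genes: int) -> list:
    return [f"g{i:04d}" for i in range(1, n_genes + 1)]


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_signatures(spec: SyntheticSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a signature table and the ground truth behind it.

    Returns a DataFrame whose first columns are :data:`META_COLS` and whose
    remaining columns are the ``n_genes`` landmark genes, plus the
    :class:`SyntheticTruth` describing the planted link.  Identical spec
    and seed give identical output.
    """
    spec.validate()
    rng_design, rng_link, rng_expr, rng_noise = _streams(spec.seed, 4)
    genes = gene_names(spec.n_genes)

    # planted link: which genes matter and with what weight
    inf_idx = np.sort(rng_link.choice(spec.n_genes, size=spec.n_informative, replace=False))
    informative = [genes[i] for i in inf_idx]
    signs = rng_link.choice([-1.0, 1.0], size=spec.n_informative)
    weights = signs * rng_link.uniform(0.75, 1.5, size=spec.n_informative)

    # experimental design: unique (cell line, drug, dose) conditions, each
    # assigned one perturbation time and replicated across batches
    shrna = spec.pert_type == "shRNA"
    doses = (None,) if shrna else spec.dose_grid
    grid = [
        (f"CL{c:02d}", f"drug{d:03d}" if not shrna else f"sh{d:03d}", dose)
        for c in range(spec.cell_lines)
        for d in range(spec.drugs)
        for dose in doses
    ]
    n_cond = math.ceil(spec.n_instances / spec.replicate_batches)
    if n_cond > len(grid):
        raise ValueError(
            f"need {n_cond} distinct conditions but the design grid has only {len(grid)}; "
            "increase cell_lines/drugs/dose_grid or replicate_batches"
        )
    cond_idx = rng_design.choice(len(grid), size=n_cond, replace=False)
    cond_time = rng_design.choice(spec.times, size=n_cond)

    rows = []
    for j, (ci, t) in enumerate(zip(cond_idx, cond_time)):
        cl, pert, dose = grid[ci]
        for b in range(spec.replicate_batches):
            rows.append((cl, pert, dose, float(t), f"b{b + 1}", j))
    rows = rows[: spec.n_instances]
    n = len(rows)

    # expression: iid N(0,1) everywhere; informative genes additionally share
    # a latent per-condition state so batch replicates are correlated
    X = rng_expr.standard_normal((n, spec.n_genes))
    if spec.n_informative and spec.replicate_rho > 0:
        z = rng_expr.standard_normal((n_cond, spec.n_informative))
        cond_of_row = np.array([r[5] for r in rows])
        rho = spec.replicate_rho
        X[:, inf_idx] = math.sqrt(rho) * z[cond_of_row] + math.sqrt(1.0 - rho) * X[:, inf_idx]

    if spec.n_informative:
        score = np.tanh(X[:, inf_idx] @ weights / math.sqrt(spec.n_informative))
    else:
        score = np.zeros(n)
    baseline = SHRNA_BASELINE if shrna else COMPOUND_BASELINE
    amplitude = SHRNA_AMPLITUDE if shrna else COMPOUND_AMPLITUDE
    clean = baseline + amplitude * score
    if not shrna and spec.dose_effect != 0.0:
        clean = clean + spec.dose_effect * np.log10([r[2] for r in rows])
    noisy = clean + rng_noise.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd else clean.copy()

    meta = pd.DataFrame(
        {
            "instance_id": [f"inst{i:05d}" for i in range(n)],
            "cell_line": [r[0] for r in rows],
            "pert_id": [r[1] for r in rows],
            "pert_type": spec.pert_type,
            "dose_um": [np.nan if shrna else r[2] for r in rows],
            "time_h": [r[3] for r in rows],
            "batch": [r[4] for r in rows],
        }
    )
    sig = pd.concat([meta, pd.DataFrame(X, columns=genes)], axis=1)
    truth = SyntheticTruth(
        informative_genes=informative,
        weights=dict(zip(informative, weights)),
        baseline=baseline,
        amplitude=amplitude,
        dose_effect=0.0 if shrna else spec.dose_effect,
        pert_type=spec.pert_type,
        viability_clean=clean,
        viability=noisy,
        instance_ids=list(meta["instance_id"]),
    )
    return sig, truth


def viability_table(signatures: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Phenotype table as a viability portal would publish it.

    One record per signature instance, keyed by (cell_line, pert_id,
    dose_um, batch) with the noisy viability readout.  The association
    stage re-joins these records to signatures and averages over batches.
    """
    return pd.DataFrame(
        {
            "cell_line": signatures["cell_line"].to_numpy(),
            "pert_id": signatures["pert_id"].to_numpy(),
            "dose_um": signatures["dose_um"].to_numpy(),
            "viability": np.asarray(truth.viability),
            "batch": signatures["batch"].to_numpy(),
        }
    )


def generate_sensitivity_table(
    spec: SyntheticSpec,
    truth: SyntheticTruth,
    signatures: pd.DataFrame,
    effect_threshold: float = 0.1,
) -> pd.DataFrame:
    """Drug-sensitivity table with GI50-style and active-area columns.

    For each (pert_id, cell_line) pair the drug's mean noise-free viability
    defines its intended effectiveness: a drug whose viability deficit
    relative to baseline exceeds ``effect_threshold`` is intended
    effective.  Effective drugs get a GI50 strictly below the maximum
    tested concentration; for a drug with no effect the GI50 is recorded at
    the highest tested concentration.  The active area grows with the
    viability deficit, so low viability maps to a large active area.
    """
    spec.validate()
    if spec.pert_type != "compound":
        raise ValueError("sensitivity tables are defined for compound screens only")
    max_conc = float(max(spec.dose_grid))
    df = pd.DataFrame(
        {
            "pert_id": signatures["pert_id"].to_numpy(),
            "cell_line": signatures["cell_line"].to_numpy(),
            "dose_um": signatures["dose_um"].to_numpy(float),
            "clean": np.asarray(truth.viability_clean),
        }
    )
    grouped = df.groupby(["pert_id", "cell_line"], sort=True)
    agg = grouped.agg(mean_viability=("clean", "mean"), dose_um=("dose_um", "max")).reset_index()
    deficit = truth.baseline - agg["mean_viability"].to_numpy()
    effective = deficit > effect_threshold
    gi50 = np.where(effective, max_conc * 10.0 ** (-3.0 * np.clip(deficit, 0.0, None)), max_conc)
    out = pd.DataFrame(
        {
            "pert_id": agg["pert_id"],
            "cell_line": agg["cell_line"],
            "dose_um": agg["dose_um"],
            "drug_sens": gi50,
            "test_max_conc": max_conc,
            "active_area": 4.0 * deficit,
            "true_viability": agg["mean_viability"],
            "intended_effective": effective,
        }
    )
    return out


def write_signatures(signatures: pd.DataFrame, path) -> None:
    signatures.to_csv(path, index=False)


def write_gct(signatures: pd.DataFrame, path) -> None:
    """Matrix-only GCT 1.2 export (instances as columns, genes as rows)."""
    genes = [c for c in signatures.columns if c not in META_COLS]
    mat = signatures[genes].to_numpy(float).T
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(genes)}\t{mat.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(signatures["instance_id"]) + "\n")
        for g, row in zip(genes, mat):
            fh.write(g + "\tna\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def spec_sidecar(spec: SyntheticSpec) -> dict:
    """Spec echoed as a plain dict for YAML/JSON sidecar files."""
    d = asdict(spec)
    d["dose_grid"] = list(d["dose_grid"])
    d["times"] = list(d["times"])
    return d
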
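"""Seeded generation of single-nucleus UMI count cohorts.

The generator reproduces the statistical structure the downstream analysis
assumes: per-cell total UMIs drawn log-normal (defaults echo the ~7,650
UMIs/cell scale of brain single-nucleus libraries), target-gene counts
negative-binomially distributed around ``basal_rate × total_umi`` with NB2
dispersion ``theta``, an optional multiplicative animal-level random effect
on the target mean, and a treated arm following one of two single-cell
knockdown architectures:

``scaled_mu``
    every treated cell's mean target count is multiplied by the residual
    fraction ``r`` (uniform partial knockdown in all cells);
``zero_subset``
    a fraction ``1 − r`` of treated cells is silenced to exactly zero while
    the rest keep the control distribution (complete knockdown in a subset).

Both architectures have the same pseudobulk mean (``r`` times control), so
bulk quantification cannot tell them apart — that is the point of the
single-cell mode comparison in :mod:`kdquant.modes`.

Filler counts are carried as a single aggregate "other" feature so that
each cell's column sum equals its drawn total exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .counts_io import ANNOTATION_COLUMNS, CountMatrix, write_annotations, write_counts

KNOCKDOWN_MODES = ("scaled_mu", "zero_subset")


@dataclass
class CellTypeSpec:
    """One cell type's generative parameters.

    Parameters
    ----------
    name
        Cell-type label.
    proportion
        Fraction of cells of this type, in [0, 1]; proportions across the
        cohort must sum to 1.
    basal_rate
        Expected target UMIs per total UMI in control cells (p > 0, < 1).
    theta
        NB2 dispersion; per-cell variance is mu + mu^2/theta.
    residual
        Residual target fraction r in (0, 1] under treatment; 1 means no
        knockdown.
    """

    name: str
    proportion: float
    basal_rate: float
    theta: float
    residual: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"proportion must be in [0,1], got {self.proportion}")
        if not 0.0 < self.basal_rate < 1.0:
            raise ValueError(f"basal_rate must be in (0,1), got {self.basal_rate}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if not 0.0 <= self.residual <= 1.0:
            raise ValueError(f"residual must be in [0,1], got {self.residual}")


@dataclass
class CohortSpec:
    """Design of a synthetic two-arm cohort.

    Defaults mirror the study design the analysis targets: 4 animals per
    arm and log-normal per-cell totals centred on 7,650 UMIs.
    """

    cell_types: list[CellTypeSpec]
    n_animals_per_arm: int = 4
    cells_per_animal: int = 2000
    total_umi_logmean: float = math.log(7650.0)
    total_umi_logsd: float = 0.5
    animal_sigma: float = 0.0
    knockdown_mode: str = "scaled_mu"
    seed: int = 0
    target_name: str = "Target"
    treatment_name: str = "ASO"
    reference_name: str = "control"
    region: str = "cerebellum"
    weeks_post_dose: float = 12.0

    def __post_init__(self) -> None:
        if self.n_animals_per_arm <= 0 or self.cells_per_animal <= 0:
            raise ValueError("animal and cell counts must be positive")
        if self.animal_sigma < 0:
            raise ValueError("animal_sigma must be >= 0")
        if self.knockdown_mode not in KNOCKDOWN_MODES:
            raise ValueError(
                f"knockdown_mode must be one of {KNOCKDOWN_MODES}, "
                f"got {self.knockdown_mode!r}"
            )
        total = sum(ct.proportion for ct in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell-type proportions sum to {total}, not 1")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        payload = yaml.safe_load(Path(path).read_text())
        payload["cell_types"] = [CellTypeSpec(**ct) for ct in payload["cell_types"]]
        return cls(**payload)


@dataclass
class SyntheticCohort:
    """A generated cohort: counts, annotations and the truth that made them."""

    counts: CountMatrix
    annotations: pd.DataFrame
    truth: CohortSpec

    def write(self, dir_path) -> dict[str, Path]:
        dir_path = Path(dir_path)
        paths = write_counts(self.counts, dir_path)
        paths["annotations"] = write_annotations(
            self.annotations, dir_path / "annotations.tsv"
        )
        paths["truth"] = self.truth.to_yaml(dir_path / "truth.yaml")
        return paths


def _draw_target_counts(
    rng: np.random.Generator, mu: np.ndarray, theta: float
) -> np.ndarray:
    """NB2 draws with mean mu and dispersion theta (variance mu + mu^2/theta)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = theta / (theta + mu[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a two-arm cohort under *spec*.

    Control cells draw target counts NB(mean = basal_rate × total_umi ×
    exp(animal effect), dispersion theta). Treated cells follow
    ``spec.knockdown_mode``. A single aggregate "other" feature makes every
    column sum equal that cell's drawn total. Identical spec and seed give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_types = len(spec.cell_types)
    props = np.array([ct.proportion for ct in spec.cell_types])
    basal = np.array([ct.basal_rate for ct in spec.cell_types])
    theta = np.array([ct.theta for ct in spec.cell_types])
    resid = np.array([ct.residual for ct in spec.cell_types])
    type_names = np.array([ct.name for ct in spec.cell_types], dtype=object)

    barcodes: list[str] = []
    rows = {k: [] for k in ("animal", "treatment", "cell_type")}
    all_target: list[np.ndarray] = []
    all_totals: list[np.ndarray] = []

    arms = [(spec.reference_name, False), (spec.treatment_name, True)]
    cell_counter = 0
    for arm_label, treated in arms:
        for a in range(spec.n_animals_per_arm):
            animal = f"{'T' if treated else 'C'}{a + 1}"
            animal_effect = rng.normal(0.0, spec.animal_sigma) if spec.animal_sigma else 0.0
            n = spec.cells_per_animal
            ct_idx = rng.choice(n_types, size=n, p=props)
            totals = np.maximum(
                np.rint(
                    rng.lognormal(spec.total_umi_logmean, spec.total_umi_logsd, size=n)
                ).astype(np.int64),
                100,
            )
            mu = basal[ct_idx] * totals * math.exp(animal_effect)
            target = np.zeros(n, dtype=np.int64)
            for t in range(n_types):
                mask = ct_idx == t
                if not mask.any():
                    continue
                if treated and spec.knockdown_mode == "scaled_mu":
                    target[mask] = _draw_target_counts(
                        rng, mu[mask] * resid[t], theta[t]
                    )
                else:
                    draws = _draw_target_counts(rng, mu[mask], theta[t])
                    if treated:  # zero_subset: silence each cell w.p. 1 - r
                        silenced = rng.random(mask.sum()) >= resid[t]
                        draws[silenced] = 0
                    target[mask] = draws
            # an NB draw can in principle exceed the cell's total; clip
            target = np.minimum(target, totals)

            barcodes.extend(
                f"cell{cell_counter + i:06d}-{animal}" for i in range(n)
            )
            cell_counter += n
            rows["animal"].extend([animal] * n)
            rows["treatment"].extend([arm_label] * n)
            rows["cell_type"].extend(type_names[ct_idx].tolist())
            all_target.append(target)
            all_totals.append(totals)

    target = np.concatenate(all_target)
    totals = np.concatenate(all_totals)
    values = sp.csc_matrix(np.vstack([target, totals - target]))
    counts = CountMatrix(values, [spec.target_name, "other"], barcodes)
    ann = pd.DataFrame(
        {
            "barcode": barcodes,
            "animal": rows["animal"],
            "treatment": rows["treatment"],
            "cell_type": rows["cell_type"],
            "region": spec.region,
            "weeks_post_dose": spec.weeks_post_dose,
        }
    )[ANNOTATION_COLUMNS]
    return SyntheticCohort(counts=counts, annotations=ann, truth=spec)


def generate_qpcr_table(
    residual_truth: float,
    n_per_arm: int,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_name: str = "control",
    treatment_name: str = "ASO",
) -> pd.DataFrame:
    """qPCR Ct fixture whose expected delta-delta-Ct residual equals
    *residual_truth*.

    Housekeeping Ct sits near 20 cycles and control-arm target Ct near 25;
    the treated arm's target Ct is shifted up by −log2(residual_truth)
    cycles, so with zero noise the 2^(−ddCt) estimate is exact.
    """
    if not 0.0 < residual_truth <= 1.0:
        raise ValueError(f"residual_truth must be in (0,1], got {residual_truth}")
    if n_per_arm <= 0:
        raise ValueError("n_per_arm must be positive")
    rng = np.random.default_rng(seed)
    shift = -math.log2(residual_truth)
    recs = []
    for arm, delta in ((reference_name, 0.0), (treatment_name, shift)):
        for i in range(n_per_arm):
            recs.append(
                {
                    "sample": f"{arm}-{i + 1}",
                    "treatment": arm,
                    "ct_target": 25.0 + delta + rng.normal(0.0, ct_noise_sd),
                    "ct_housekeeping": 20.0 + rng.normal(0.0, ct_noise_sd),
                }
            )
    return pd.DataFrame.from_records(recs)
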
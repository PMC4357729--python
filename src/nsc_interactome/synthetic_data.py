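"""Synthetic AP-MS data with known ground truth for end-to-end verification.

Generates spectral-count matrices, GO annotations and PPI edge lists whose
statistical structure matches what the analysis assumes, so every pipeline
stage can be exercised and benchmarked without the original raw data:

* per-protein base abundance lambda is log-uniform; the differentiating /
  proliferating rates are lambda * 2^(+-delta/2) where delta is a signed
  true log2 effect for a minority of proteins (defaults: 10% up, 7% down,
  |delta| uniform in [0.8, 2.5]) plus a small lognormal biological
  perturbation; counts are Poisson per cytoplasmic/nuclear fraction;
* the negative control is sparse: a small fraction of proteins
  (default 29/2641) are genuine background binders with Poisson counts;
* log2-ratio noise therefore decreases with intensity (Poisson counting
  noise ~ 2/sqrt(lambda) in log2 units plus the intensity-independent
  sigma0) — exactly the heteroscedastic regime in which intensity binning
  matters; :func:`generate_null_ratios` exposes the same noise law
  sigma(I) = sigma0 + sigma1 / sqrt(2^I) directly for calibration studies;
* GO terms are assigned at random, with a few spiked terms preferentially
  annotating the true up-regulated proteins; the PPI graph is a sparse
  random graph over all proteins with guaranteed physical attachment of
  seeds and a share of non-physical edge types for filter testing.

A single integer seed drives independent substreams for counts,
annotations and the PPI graph, so regenerating one artifact never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .iotables import AnnotationMap, CountMatrix, EdgeList

_COUNT_STREAM, _GO_STREAM, _PPI_STREAM = 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    Scale defaults mirror the pull-down magnitudes the pipeline targets
    (~2641 proteins, ~29 genuine control binders); effect and noise
    defaults are the regime the differential caller is designed for.
    """

    n_proteins: int = 2641
    control_fraction: float = 29.0 / 2641.0  # genuine background binders
    lambda_control: float = 4.0              # their control Poisson rate
    lambda_min: float = 2.0                  # NSC base rate, log-uniform
    lambda_max: float = 200.0
    fraction_split: float = 0.6              # cytoplasmic share of each NSC rate
    pi_up: float = 0.10                      # fraction truly up in differentiation
    pi_down: float = 0.07                    # fraction truly up in maintenance
    effect_min: float = 0.8                  # |delta| uniform in [min, max], log2
    effect_max: float = 2.5
    sigma0: float = 0.1    # intensity-independent log2-ratio noise
    sigma1: float = 2.0    # intensity-dependent: sigma(I) = sigma0 + sigma1/sqrt(2^I)
    n_go_terms: int = 200
    n_spiked_terms: int = 5
    spike_odds: float = 10.0                 # sampling odds of true-up proteins
    spiked_term_size: int = 50               # spike-ins are fixed-size positive controls
    term_size_min: int = 5
    term_size_max: int = 100
    ppi_density: float = 0.002               # random-graph edge probability
    seed_attachment: float = 1.0             # share of seeds forced to have a pp edge
    nonphysical_share: float = 0.2           # 'transcription regulation'/'transport'

    def __post_init__(self) -> None:
        fracs = {"control_fraction": self.control_fraction,
                 "fraction_split": self.fraction_split,
                 "seed_attachment": self.seed_attachment,
                 "nonphysical_share": self.nonphysical_share,
                 "ppi_density": self.ppi_density}
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pi_up < 0 or self.pi_down < 0 or self.pi_up + self.pi_down >= 1:
            raise ValueError("pi_up + pi_down must be < 1 with both nonnegative")
        if not 0 < self.lambda_min <= self.lambda_max:
            raise ValueError("need 0 < lambda_min <= lambda_max")
        if not 0 <= self.effect_min <= self.effect_max:
            raise ValueError("need 0 <= effect_min <= effect_max")
        if self.sigma0 < 0 or self.sigma1 < 0 or self.sigma0 + self.sigma1 == 0:
            raise ValueError("noise scale must be positive")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if not 1 <= self.term_size_min <= self.term_size_max <= self.n_proteins:
            raise ValueError("term sizes must satisfy 1 <= min <= max <= n_proteins")
        if not 1 <= self.spiked_term_size <= self.n_proteins:
            raise ValueError("spiked_term_size must be in [1, n_proteins]")


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed by protein / term."""

    proteins: pd.DataFrame       # protein_id, lambda, in_control, true_log2fc, enriched_truth
    spiked_terms: set[str] = field(default_factory=set)
    seed_truth: set[str] = field(default_factory=set)

    @property
    def true_up(self) -> set[str]:
        sel = self.proteins["true_log2fc"] > 0
        return set(self.proteins.loc[sel, "protein_id"])

    @property
    def true_down(self) -> set[str]:
        sel = self.proteins["true_log2fc"] < 0
        return set(self.proteins.loc[sel, "protein_id"])


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _protein_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_counts(cfg: SimConfig, seed: int) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the three-sample spectral-count table.

    Returns an unmerged :class:`CountMatrix` (NSC samples split into
    cytoplasmic/nuclear fractions, the control as a single "whole"
    fraction) holding only identified rows (count > 0), plus the ground
    truth.  Deterministic given (cfg, seed).
    """
    rng = _rng(seed, _COUNT_STREAM)
    n = cfg.n_proteins
    ids = _protein_ids(n)

    lam = np.exp(rng.uniform(np.log(cfg.lambda_min), np.log(cfg.lambda_max), n))
    role = rng.choice(
        np.array(["up", "down", "null"]),
        size=n,
        p=[cfg.pi_up, cfg.pi_down, 1.0 - cfg.pi_up - cfg.pi_down],
    )
    delta = np.zeros(n)
    eff = rng.uniform(cfg.effect_min, cfg.effect_max, n)
    delta[role == "up"] = eff[role == "up"]
    delta[role == "down"] = -eff[role == "down"]
    # intensity-independent biological perturbation of the true ratio
    delta_obs = delta + rng.normal(0.0, cfg.sigma0, n)

    rate_d = lam * np.exp2(delta_obs / 2.0)
    rate_p = lam * np.exp2(-delta_obs / 2.0)
    in_control = rng.random(n) < cfg.control_fraction

    rows: list[tuple[str, str, str, int]] = []
    split = cfg.fraction_split
    for sample, rate in (("differentiating", rate_d), ("proliferating", rate_p)):
        cyto = rng.poisson(rate * split)
        nuc = rng.poisson(rate * (1.0 - split))
        for i, pid in enumerate(ids):
            if cyto[i] > 0:
                rows.append((pid, sample, "cytoplasmic", int(cyto[i])))
            if nuc[i] > 0:
                rows.append((pid, sample, "nuclear", int(nuc[i])))
    ctrl = np.where(in_control, rng.poisson(cfg.lambda_control, n), 0)
    for i, pid in enumerate(ids):
        if ctrl[i] > 0:
            rows.append((pid, "control", "whole", int(ctrl[i])))

    data = pd.DataFrame(rows, columns=["protein_id", "sample", "fraction", "count"])
    truth = GroundTruth(
        proteins=pd.DataFrame({
            "protein_id": ids,
            "lambda": lam,
            "in_control": in_control,
            "true_log2fc": delta,
            "enriched_truth": ~in_control,
        }),
    )
    truth.seed_truth = set(truth.proteins.loc[~in_control, "protein_id"])
    return CountMatrix(data, merged=False), truth


def generate_null_ratios(n: int, cfg: SimConfig, seed: int,
                         ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Null (intensity, log2 ratio) pairs under the generator's noise law.

    Intensities are log2 of the log-uniform base abundance; ratios are
    centered normal with SD sigma(I) = sigma0 + sigma1 / sqrt(2^I).
    Feed directly to :func:`~nsc_interactome.differential.standardize_ratios`
    for calibration studies of the binned z-test.
    """
    rng = _rng(seed, _COUNT_STREAM)
    lam = np.exp(rng.uniform(np.log(cfg.lambda_min), np.log(cfg.lambda_max), n))
    intensity = np.log2(lam)
    sigma = cfg.sigma0 + cfg.sigma1 / np.sqrt(np.exp2(intensity))
    ratios = rng.normal(0.0, sigma)
    return _protein_ids(n), intensity, ratios


def generate_annotations(cfg: SimConfig, truth: GroundTruth, seed: int) -> AnnotationMap:
    """Random GO-term assignment with spiked terms biased toward true-up proteins.

    Background term sizes are log-uniform in [term_size_min,
    term_size_max]; spiked terms are fixed-size (``spiked_term_size``)
    positive controls that sample members with ``spike_odds`` : 1
    weighting in favor of proteins with a true positive effect (odds 1 =
    no preference, a null spike).  Term ids are "GO:SIM...."; spiked
    terms carry names marking them as synthetic spikes.
    """
    rng = _rng(seed, _GO_STREAM)
    ids = list(truth.proteins["protein_id"])
    n = len(ids)
    up = truth.proteins["true_log2fc"].to_numpy() > 0
    base_w = np.ones(n)
    spike_w = np.where(up, cfg.spike_odds, 1.0)

    mapping: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    spiked: set[str] = set()
    for j in range(1, cfg.n_go_terms + 1):
        term = f"GO:SIM{j:04d}"
        is_spiked = j <= cfg.n_spiked_terms
        if is_spiked:
            size = min(cfg.spiked_term_size, n)
        else:
            size = int(round(np.exp(rng.uniform(
                np.log(cfg.term_size_min), np.log(cfg.term_size_max)))))
            size = min(max(size, cfg.term_size_min), min(cfg.term_size_max, n))
        w = spike_w if is_spiked else base_w
        members = rng.choice(n, size=size, replace=False, p=w / w.sum())
        for m in members:
            mapping.setdefault(ids[m], set()).add(term)
        names[term] = (f"synthetic spiked process {j}" if is_spiked
                       else f"synthetic background process {j}")
        if is_spiked:
            spiked.add(term)
    truth.spiked_terms = spiked
    return AnnotationMap(mapping, names)


def generate_ppi(cfg: SimConfig, truth: GroundTruth, seed: int,
                 seeds: Iterable[str] | None = None) -> EdgeList:
    """Sparse random PPI edge list over all proteins.

    Edges are sampled as a G(n, p) graph with ``ppi_density``;
    ``nonphysical_share`` of them get a non-physical type
    ('transcription regulation' or 'transport'), the rest are physical
    ('pp').  A ``seed_attachment`` share of the seed proteins (default:
    the truly enriched set) is guaranteed at least one physical edge.
    """
    rng = _rng(seed, _PPI_STREAM)
    ids = list(truth.proteins["protein_id"])
    n = len(ids)
    seeds = sorted(truth.seed_truth if seeds is None else set(seeds))

    n_pairs = n * (n - 1) // 2
    n_edges = rng.binomial(n_pairs, cfg.ppi_density)
    # sample unordered pairs without materializing all n*(n-1)/2 of them
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_edges:
        a, b = rng.integers(0, n, 2)
        if a != b:
            chosen.add((min(a, b), max(a, b)))
    pair_list = sorted(chosen)
    types = rng.choice(
        np.array(["pp", "transcription regulation", "transport"]),
        size=len(pair_list),
        p=[1.0 - cfg.nonphysical_share, cfg.nonphysical_share / 2.0,
           cfg.nonphysical_share / 2.0],
    )
    edges = [(ids[a], str(t), ids[b]) for (a, b), t in zip(pair_list, types)]

    physical_deg: dict[str, int] = {}
    for a, t, b in edges:
        if t == "pp":
            physical_deg[a] = physical_deg.get(a, 0) + 1
            physical_deg[b] = physical_deg.get(b, 0) + 1
    idx = {p: i for i, p in enumerate(ids)}
    for s in seeds:
        if rng.random() < cfg.seed_attachment and physical_deg.get(s, 0) == 0:
            partner = ids[int(rng.integers(0, n - 1))]
            if partner == s:
                partner = ids[(idx[s] + 1) % n]
            edges.append((s, "pp", partner))
            physical_deg[s] = 1
    return EdgeList(edges)
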
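"""Synthetic count matrices with the statistical structure of a whole-cell
spike-in starvation experiment, with recorded ground truth.

The generator emulates an *E. coli* K-12 transcriptome sampled in triplicate
during steady-state growth and at five time points of amino-acid starvation,
with three plasmid-borne spike-in features dosed at a constant amount per OD
unit of culture:

* read composition at steady state dominated by rRNA (89% of chromosomal
  reads by default), with tRNA strongly under-captured as in real libraries;
* a decaying rRNA pool (to 70% of pre-starvation at 80 min by default) and a
  decaying total mRNA pool (70% at 10 min, 50% at 80 min);
* per-gene regulation drawn on two temporal archetypes — a *step* (abrupt
  shift held for the rest of the starvation) and a *surge* (spike at 5 min
  followed by recovery and overshoot) — with log-normal fold-change
  magnitudes, renormalized within the mRNA class so the programmed pool
  curve is exact in expectation;
* spike-in reads at a constant expected abundance per OD, so their share of
  a sample's reads grows as the cellular pool shrinks;
* an optional mid-series handling artifact (chromosomal reads inflated or
  deflated in one sample) to exercise the QC outlier detection;
* an optional rifampicin tail appended after the last starvation sample, in
  which transcription-dependent classes decay further (tRNA-mapped signal to
  2% of pre-starvation by default) while rRNA stays at its 80-min level.

Counts are multinomial given a per-sample depth drawn uniformly from the
configured range (Poisson-like at these depths); an optional
Dirichlet-multinomial concentration adds between-replicate overdispersion.
Everything is reproducible from the seed; there is no hidden global
randomness.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, RRNA_CLASSES, write_counts


def _default_rrna_curve() -> dict[float, float]:
    return {5: 0.97, 10: 0.93, 20: 0.85, 40: 0.78, 80: 0.70}


def _default_mrna_curve() -> dict[float, float]:
    return {5: 0.80, 10: 0.70, 20: 0.63, 40: 0.56, 80: 0.50}


def _default_trna_curve() -> dict[float, float]:
    return {5: 0.35, 10: 0.25, 20: 0.18, 40: 0.12, 80: 0.08}


def _default_srna_curve() -> dict[float, float]:
    return {5: 0.85, 10: 0.75, 20: 0.68, 40: 0.60, 80: 0.55}


def _default_other_curve() -> dict[float, float]:
    return {5: 1.0, 10: 1.0, 20: 1.0, 40: 1.0, 80: 1.0}


def _default_class_fractions() -> dict[str, float]:
    return {"rRNA": 0.89, "tRNA": 0.0027, "sRNA": 0.010, "other_ncRNA": 0.0022}


def _default_profile_mixture() -> dict[str, float]:
    return {"step": 0.85, "spike": 0.15}


def _default_step_shape() -> dict[float, float]:
    return {5: 1.0, 10: 1.0, 20: 1.0, 40: 1.0, 80: 1.0}


def _default_spike_shape() -> dict[float, float]:
    # starvation values sum to zero over the retained time points (5, 10,
    # 40, 80 min) so the surge archetype is orthogonal to the step archetype
    # after per-gene mean normalization and centering
    return {5: 1.0, 10: 0.0, 20: -0.2, 40: -0.4, 80: -0.6}


def _default_rif_tail() -> dict[str, dict[float, float]]:
    return {
        "rRNA": {90: 0.70, 95: 0.70, 105: 0.70, 125: 0.70},
        "tRNA": {90: 0.05, 95: 0.04, 105: 0.03, 125: 0.02},
        "mRNA": {90: 0.30, 95: 0.20, 105: 0.10, 125: 0.04},
        "sRNA": {90: 0.35, 95: 0.25, 105: 0.15, 125: 0.06},
        "other_ncRNA": {90: 1.0, 95: 1.0, 105: 1.0, 125: 1.0},
    }


@dataclasses.dataclass
class SynthConfig:
    """Study conditions for the generator; defaults emulate the experiment."""

    n_mrna_genes: int = 3919
    n_trna: int = 86
    n_srna: int = 18
    n_other_nc: int = 3
    rrna_copies: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"rRNA_16S": 7, "rRNA_23S": 7, "rRNA_5S": 8}
    )
    rrna_lengths: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"rRNA_16S": 1542, "rRNA_23S": 2904, "rRNA_5S": 120}
    )
    spike_features: tuple[tuple[str, int], ...] = (
        ("qrr2", 107),
        ("bla", 861),
        ("anti_lacI", 1083),
    )
    spike_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    read_depth_range: tuple[int, int] = (100_000, 1_000_000)
    class_read_fraction_steady: Mapping[str, float] = dataclasses.field(
        default_factory=_default_class_fractions
    )
    spikein_read_fraction_steady: float = 0.010
    steady_times: tuple[float, ...] = (-20.0, -10.0, 0.0)
    starvation_times: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0)
    rrna_retention_curve: Mapping[float, float] = dataclasses.field(
        default_factory=_default_rrna_curve
    )
    mrna_pool_curve: Mapping[float, float] = dataclasses.field(
        default_factory=_default_mrna_curve
    )
    trna_pool_curve: Mapping[float, float] = dataclasses.field(
        default_factory=_default_trna_curve
    )
    srna_pool_curve: Mapping[float, float] = dataclasses.field(
        default_factory=_default_srna_curve
    )
    other_nc_pool_curve: Mapping[float, float] = dataclasses.field(
        default_factory=_default_other_curve
    )
    fraction_up: float = 0.10
    fraction_down: float = 0.60
    fc_log2_median: float = 0.8
    fc_log2_sigma: float = 0.7
    profile_mixture: Mapping[str, float] = dataclasses.field(
        default_factory=_default_profile_mixture
    )
    step_shape: Mapping[float, float] = dataclasses.field(
        default_factory=_default_step_shape
    )
    spike_shape: Mapping[float, float] = dataclasses.field(
        default_factory=_default_spike_shape
    )
    baseline_sigma: float = 1.0
    outlier_sample: str | None = "starv_20"
    outlier_deflation: float = -0.43  # negative = chromosomal reads inflated
    dirichlet_concentration: float | None = None
    trna_capture_prob: float | None = None  # None: configured tRNA share used as-is
    trna_molar_read_fraction: float = 0.09  # tRNA share if capture were perfect
    rifampicin_times: tuple[float, ...] = (90.0, 95.0, 105.0, 125.0)
    rifampicin_tail: Mapping[str, Mapping[float, float]] = dataclasses.field(
        default_factory=_default_rif_tail
    )
    seed: int = 0

    # -- derived -----------------------------------------------------------
    @property
    def n_rrna(self) -> int:
        return sum(self.rrna_copies.values())

    @property
    def n_genes(self) -> int:
        return (
            self.n_mrna_genes + self.n_trna + self.n_srna + self.n_other_nc + self.n_rrna
        )

    def validate(self) -> None:
        for name in ("fraction_up", "fraction_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fraction_up + self.fraction_down > 1:
            raise ValueError("fraction_up + fraction_down must not exceed 1")
        if not 0 < self.spikein_read_fraction_steady < 1:
            raise ValueError("spikein_read_fraction_steady must lie in (0, 1)")
        fr = dict(self.class_read_fraction_steady)
        if any(not 0 <= v <= 1 for v in fr.values()) or sum(fr.values()) >= 1:
            raise ValueError("class read fractions must lie in [0, 1] and sum < 1")
        lo, hi = self.read_depth_range
        if lo > hi or lo <= 0:
            raise ValueError("invalid read_depth_range")
        if lo < 10 * self.n_genes:
            raise ValueError(
                f"read depth ({lo}) must be at least 10x the gene count "
                f"({self.n_genes})"
            )
        for label, curve in self._class_curves().items():
            missing = set(map(float, self.starvation_times)) - set(
                map(float, curve.keys())
            )
            if missing:
                raise ValueError(f"{label} pool curve missing times {sorted(missing)}")
        if abs(sum(self.profile_mixture.values()) - 1) > 1e-9:
            raise ValueError("profile_mixture weights must sum to 1")

    def _class_curves(self) -> dict[str, Mapping[float, float]]:
        return {
            "rRNA": self.rrna_retention_curve,
            "mRNA": self.mrna_pool_curve,
            "tRNA": self.trna_pool_curve,
            "sRNA": self.srna_pool_curve,
            "other_ncRNA": self.other_nc_pool_curve,
        }

    def class_curve(self, rna_class: str, time: float) -> float:
        label = "rRNA" if rna_class in RRNA_CLASSES else rna_class
        return float(self._class_curves()[label][time])


def null_config(**overrides) -> SynthConfig:
    """A no-signal configuration: flat pools, no regulation, no artifact."""
    flat = {t: 1.0 for t in (5.0, 10.0, 20.0, 40.0, 80.0)}
    base = dict(
        rrna_retention_curve=dict(flat),
        mrna_pool_curve=dict(flat),
        trna_pool_curve=dict(flat),
        srna_pool_curve=dict(flat),
        other_nc_pool_curve=dict(flat),
        fraction_up=0.0,
        fraction_down=0.0,
        outlier_sample=None,
    )
    base.update(overrides)
    return SynthConfig(**base)


@dataclasses.dataclass
class GroundTruth:
    """True per-gene temporal profiles and per-sample scale factors.

    ``gene_truth``: per gene, the RNA class, baseline abundance weight,
    planted archetype and signed log2 magnitude, plus the expected relative
    abundance (``rel_<sample>``; 1 at steady state) and true log2 fold change
    (``log2fc_<sample>``) at every non-steady sample.

    ``sample_truth``: per sample, the drawn depth, the biological total-RNA
    scale factor (chromosomal abundance relative to steady state), the
    handling-artifact scale applied on top, and the expected spike-in read
    fraction.
    """

    gene_truth: pd.DataFrame
    sample_truth: pd.DataFrame


class _Model:
    """Deterministic expectation model shared by base and tail simulation."""

    def __init__(self, config: SynthConfig, seed: int | None):
        config.validate()
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)
        self._build_annotation()
        self._draw_baselines()
        self._draw_regulation()

    def _build_annotation(self) -> None:
        cfg = self.config
        rng = self.rng
        ids: list[str] = []
        lengths: list[int] = []
        classes: list[str] = []
        for cls, n in cfg.rrna_copies.items():
            tag = {"rRNA_16S": "rrs", "rRNA_23S": "rrl", "rRNA_5S": "rrf"}[cls]
            for i in range(n):
                ids.append(f"{tag}_{i + 1}")
                lengths.append(int(cfg.rrna_lengths[cls]))
                classes.append(cls)
        for i in range(cfg.n_trna):
            ids.append(f"tRNA_{i + 1:03d}")
            lengths.append(int(rng.integers(74, 94)))
            classes.append("tRNA")
        for i in range(cfg.n_srna):
            ids.append(f"sRNA_{i + 1:02d}")
            lengths.append(int(rng.integers(50, 301)))
            classes.append("sRNA")
        other_names = ["rnpB", "ssrS", "ffs", "ssrA", "csrB", "csrC"]
        for i in range(cfg.n_other_nc):
            name = other_names[i] if i < len(other_names) else f"ncRNA_{i + 1}"
            ids.append(name)
            lengths.append(int(rng.integers(80, 401)))
            classes.append("other_ncRNA")
        for i in range(cfg.n_mrna_genes):
            ids.append(f"g{i + 1:04d}")
            lengths.append(int(np.clip(rng.lognormal(np.log(850), 0.55), 90, 8000)))
            classes.append("mRNA")
        # one chromosomal gene shares sequence with the spike-in plasmid
        if cfg.n_mrna_genes >= 100:
            ids[ids.index("g0100")] = "lacI"
        ann = pd.DataFrame(
            {
                "length_bp": lengths,
                "rna_class": classes,
                "origin": "chromosome",
            },
            index=pd.Index(ids, name="gene_id"),
        )
        spike = pd.DataFrame(
            {
                "length_bp": [length for _, length in cfg.spike_features],
                "rna_class": "spike_in_feature",
                "origin": "plasmid",
            },
            index=pd.Index(
                [fid for fid, _ in cfg.spike_features], name="gene_id"
            ),
        )
        self.annotation = pd.concat([ann, spike])
        self.chrom_genes = ann.index
        self.spike_ids = spike.index

    def _draw_baselines(self) -> None:
        """Steady-state abundance weights; chromosomal total is 1."""
        cfg = self.config
        rng = self.rng
        ann = self.annotation.loc[self.chrom_genes]
        shares = dict(cfg.class_read_fraction_steady)
        trna_share = shares["tRNA"]
        if cfg.trna_capture_prob is not None:
            # capture bias: reads reflect only the captured fraction of the
            # molar tRNA pool
            trna_share = cfg.trna_molar_read_fraction * cfg.trna_capture_prob
        rrna_total = shares["rRNA"]
        # split rRNA among species by copy number x length (mass share)
        mass = {
            cls: cfg.rrna_copies[cls] * cfg.rrna_lengths[cls]
            for cls in cfg.rrna_copies
        }
        mass_total = sum(mass.values())
        class_share = {
            cls: rrna_total * mass[cls] / mass_total for cls in mass
        }
        class_share["tRNA"] = trna_share
        class_share["sRNA"] = shares["sRNA"]
        class_share["other_ncRNA"] = shares["other_ncRNA"]
        class_share["mRNA"] = 1.0 - sum(class_share.values())
        baseline = pd.Series(0.0, index=self.chrom_genes)
        for cls, share in class_share.items():
            members = ann.index[ann["rna_class"] == cls]
            if len(members) == 0:
                continue
            if cls in RRNA_CLASSES:
                w = np.ones(len(members))  # operon copies are equivalent
            else:
                w = rng.lognormal(0.0, cfg.baseline_sigma, len(members))
            baseline[members] = share * w / w.sum()
        self.baseline = baseline
        spike_total = cfg.spikein_read_fraction_steady / (
            1.0 - cfg.spikein_read_fraction_steady
        )
        w = np.asarray(cfg.spike_weights, dtype=float)
        self.spike_abundance = pd.Series(
            spike_total * w / w.sum(), index=self.spike_ids
        )

    def _draw_regulation(self) -> None:
        """Assign archetypes and signed log2 magnitudes to mRNA genes."""
        cfg = self.config
        rng = self.rng
        ann = self.annotation.loc[self.chrom_genes]
        mrna = ann.index[ann["rna_class"] == "mRNA"]
        n = len(mrna)
        n_up = int(round(cfg.fraction_up * n))
        n_down = int(round(cfg.fraction_down * n))
        order = rng.permutation(n)
        up_idx = mrna[order[:n_up]]
        down_idx = mrna[order[n_up : n_up + n_down]]
        archetype = pd.Series("none", index=self.chrom_genes, name="archetype")
        magnitude = pd.Series(0.0, index=self.chrom_genes, name="log2_magnitude")
        labels = list(cfg.profile_mixture)
        probs = np.asarray([cfg.profile_mixture[k] for k in labels], dtype=float)
        for genes, sign in ((up_idx, 1.0), (down_idx, -1.0)):
            if len(genes) == 0:
                continue
            archetype[genes] = rng.choice(labels, size=len(genes), p=probs)
            magnitude[genes] = sign * rng.lognormal(
                np.log(cfg.fc_log2_median), cfg.fc_log2_sigma, len(genes)
            )
        self.archetype = archetype
        self.magnitude = magnitude

    # -- expectations ------------------------------------------------------
    def _shape_value(self, gene_archetype: str, time: float) -> float:
        cfg = self.config
        if gene_archetype == "step":
            return float(cfg.step_shape[time])
        if gene_archetype == "spike":
            return float(cfg.spike_shape[time])
        return 0.0

    def relative_abundance(self, time: float, condition: str) -> pd.Series:
        """Expected abundance per OD relative to steady state, per gene."""
        cfg = self.config
        if condition == "steady_state":
            return pd.Series(1.0, index=self.chrom_genes)
        ann = self.annotation.loc[self.chrom_genes]
        rel = pd.Series(1.0, index=self.chrom_genes)
        if condition == "starvation":
            for cls in ann["rna_class"].unique():
                members = ann.index[ann["rna_class"] == cls]
                rel[members] = cfg.class_curve(cls, time)
            mrna = ann.index[ann["rna_class"] == "mRNA"]
            shape = np.array(
                [self._shape_value(self.archetype[g], time) for g in mrna]
            )
            r = np.power(2.0, self.magnitude[mrna].to_numpy() * shape)
            base = self.baseline[mrna].to_numpy()
            z = base.sum() / float((base * r).sum())
            rel[mrna] *= r * z
            return rel
        if condition == "rifampicin":
            t80 = float(max(cfg.starvation_times))
            rel80 = self.relative_abundance(t80, "starvation")
            tail = cfg.rifampicin_tail
            for cls in ann["rna_class"].unique():
                members = ann.index[ann["rna_class"] == cls]
                label = "rRNA" if cls in RRNA_CLASSES else cls
                curve80 = cfg.class_curve(cls, t80)
                rel[members] = (
                    float(tail[label][time]) * rel80[members] / curve80
                )
            return rel
        raise ValueError(f"unknown condition: {condition}")


def _sample_table(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    steady_ods = (0.40, 0.45, 0.50)
    for i, t in enumerate(cfg.steady_times):
        rows.append((f"steady_{i + 1}", t, "steady_state", steady_ods[i % 3]))
    for j, t in enumerate(cfg.starvation_times):
        rows.append((f"starv_{int(t)}", t, "starvation", 0.52 + 0.01 * j))
    df = pd.DataFrame(
        rows, columns=["sample_id", "time_min", "condition", "od_at_harvest"]
    ).set_index("sample_id")
    df["is_outlier"] = False
    return df


def _draw_counts(model: _Model, samples: pd.DataFrame) -> tuple[pd.DataFrame, GroundTruth]:
    cfg = model.config
    rng = model.rng
    genes = model.chrom_genes.append(model.spike_ids)
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    rel_cols: dict[str, pd.Series] = {}
    sample_rows = []
    for j, (sid, meta) in enumerate(samples.iterrows()):
        # depth and counts are drawn per sample, in sample order, so a run
        # with appended samples reproduces the base samples bit-for-bit
        depth = int(
            rng.integers(cfg.read_depth_range[0], cfg.read_depth_range[1] + 1)
        )
        rel = model.relative_abundance(meta["time_min"], meta["condition"])
        rel_cols[sid] = rel
        abundance = model.baseline * rel
        total_scale = float(abundance.sum())
        artifact = 1.0
        if cfg.outlier_sample == sid:
            artifact = 1.0 - cfg.outlier_deflation
        chrom = abundance.to_numpy() * artifact
        spike = model.spike_abundance.to_numpy()
        p = np.concatenate([chrom, spike])
        p = p / p.sum()
        if cfg.dirichlet_concentration is not None:
            p = rng.dirichlet(cfg.dirichlet_concentration * p)
        counts[:, j] = rng.multinomial(depth, p)
        sample_rows.append(
            {
                "sample_id": sid,
                "depth": depth,
                "total_scale": total_scale,
                "artifact_scale": artifact,
                "expected_spike_fraction": float(spike.sum() / (chrom.sum() + spike.sum())),
            }
        )
    counts_df = pd.DataFrame(counts, index=genes, columns=samples.index)
    counts_df.index.name = "gene_id"

    gene_truth = pd.DataFrame(
        {
            "rna_class": model.annotation.loc[model.chrom_genes, "rna_class"],
            "baseline": model.baseline,
            "archetype": model.archetype,
            "log2_magnitude": model.magnitude,
        }
    )
    non_steady = samples.index[samples["condition"] != "steady_state"]
    for sid in non_steady:
        gene_truth[f"rel_{sid}"] = rel_cols[sid]
        gene_truth[f"log2fc_{sid}"] = np.log2(rel_cols[sid])
    gene_truth.index.name = "gene_id"
    sample_truth = pd.DataFrame(sample_rows).set_index("sample_id")
    return counts_df, GroundTruth(gene_truth=gene_truth, sample_truth=sample_truth)


def simulate_experiment(
    config: SynthConfig | None = None, seed: int | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the steady-state + starvation series; reproducible from seed."""
    cfg = config or SynthConfig()
    model = _Model(cfg, seed)
    samples = _sample_table(cfg)
    counts, truth = _draw_counts(model, samples)
    matrix = CountMatrix(counts, model.annotation.copy(), samples)
    return matrix, truth


def simulate_rifampicin_tail(
    config: SynthConfig | None = None,
    seed: int | None = None,
    tail_times: Sequence[float] | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Base series plus rifampicin samples in which new synthesis is blocked.

    The base portion is bit-identical to :func:`simulate_experiment` with the
    same config and seed; tail samples are appended after it.
    """
    cfg = config or SynthConfig()
    times = tuple(float(t) for t in (tail_times or cfg.rifampicin_times))
    t_last = float(max(cfg.starvation_times))
    bad = [t for t in times if t <= t_last]
    if bad:
        raise ValueError(
            f"rifampicin tail times must come after the last starvation sample "
            f"({t_last} min): {bad}"
        )
    for label, curve in cfg.rifampicin_tail.items():
        missing = set(times) - set(map(float, curve.keys()))
        if missing:
            raise ValueError(f"rifampicin tail curve {label} missing {sorted(missing)}")
    model = _Model(cfg, seed)
    samples = _sample_table(cfg)
    tail = pd.DataFrame(
        {
            "time_min": list(times),
            "condition": "rifampicin",
            "od_at_harvest": 0.57,
            "is_outlier": False,
        },
        index=pd.Index([f"rif_{int(t)}" for t in times], name="sample_id"),
    )
    all_samples = pd.concat([samples, tail])
    counts, truth = _draw_counts(model, all_samples)
    matrix = CountMatrix(counts, model.annotation.copy(), all_samples)
    return matrix, truth


def write_fixture(
    dir_path: str | Path, matrix: CountMatrix, truth: GroundTruth
) -> dict[str, Path]:
    """Write the fixture TSVs (counts, annotation, metadata, ground truth)."""
    directory = Path(dir_path)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "annotation": directory / "annotation.tsv",
        "samples": directory / "samples.tsv",
        "gene_truth": directory / "gene_truth.tsv",
        "sample_truth": directory / "sample_truth.tsv",
    }
    write_counts(matrix, paths["counts"], paths["annotation"], paths["samples"])
    truth.gene_truth.to_csv(paths["gene_truth"], sep="\t")
    truth.sample_truth.to_csv(paths["sample_truth"], sep="\t")
    return paths
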
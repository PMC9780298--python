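"""Synthetic panel-sequencing cohorts with known ground truth.

Everything downstream of alignment/calling in a liquid-biopsy panel study —
per-target read counts with GC bias, somatic calls with beta-distributed VAFs,
gene-level copy-number states, dosage-coupled expression, and exponential
survival — can be emulated here so that the instability metrics, the response
discrimination and the survival signature are testable without access to
restricted human data.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDesign",
    "CnvEvent",
    "CohortTruth",
    "BinCountSet",
    "generate_panel",
    "generate_bin_counts",
    "generate_variants",
    "generate_cnv_states",
    "generate_expression_survival",
]

PANEL_COLUMNS = ["chrom", "start", "end", "gene", "gc_fraction"]


@dataclass(frozen=True)
class PanelDesign:
    """A capture panel: ordered, non-overlapping target bins with GC content.

    ``bins`` has columns chrom, start, end (0-based half-open), gene,
    gc_fraction. The exonic base total (the TMB denominator) is the sum of
    bin lengths.
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        b = self.bins
        missing = [c for c in PANEL_COLUMNS if c not in b.columns]
        if missing:
            raise ValueError(f"panel bins missing columns: {missing}")
        if (b["start"] >= b["end"]).any():
            raise ValueError("every bin must satisfy start < end")
        if ((b["gc_fraction"] < 0) | (b["gc_fraction"] > 1)).any():
            raise ValueError("gc_fraction must lie in [0, 1]")
        for _, grp in b.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (np.diff(starts) > 0).all():
                raise ValueError("bins must be sorted by (chrom, start)")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError("bins on a chromosome must not overlap")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    @property
    def exonic_base_total(self) -> int:
        return int(self.lengths.sum())

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PanelDesign":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class CnvEvent:
    """A planted copy-number event: multiplier 1.0 encodes no event."""

    sample: str
    chrom: str
    start: int
    end: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("copy-ratio multiplier must be positive")


@dataclass
class CohortTruth:
    """Ground truth recorded by the generators, for recovery tests."""

    seed: int
    cnv_events: list[CnvEvent] = field(default_factory=list)
    ignored_events: list[CnvEvent] = field(default_factory=list)
    true_mutation_counts: dict[str, int] = field(default_factory=dict)
    contaminants: pd.DataFrame | None = None
    dosage_slope: float | None = None
    hazard_ratio: float | None = None
    group_labels: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.contaminants is not None:
            d["contaminants"] = self.contaminants.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


@dataclass
class BinCountSet:
    """Raw per-bin read counts for a baseline cohort plus test samples."""

    panel: PanelDesign
    counts: pd.DataFrame  # bins x samples
    baseline_samples: list[str]
    test_samples: list[str]

    def to_tsv(self, path) -> None:
        out = pd.concat([self.panel.bins.reset_index(drop=True), self.counts.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)


def generate_panel(
    n_bins: int,
    bin_length: int = 200,
    gc_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    chrom: str = "chr1",
    gap: int = 300,
) -> PanelDesign:
    """Lay out ``n_bins`` equal-length, non-overlapping target bins on one
    chromosome with GC fractions drawn uniformly from ``gc_range``."""
    if n_bins < 1 or bin_length < 1:
        raise ValueError("n_bins and bin_length must be positive")
    lo, hi = gc_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("gc_range must be an interval within [0, 1]")
    rng = np.random.default_rng(seed)
    starts = np.arange(n_bins) * (bin_length + gap) + 1000
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_length,
            "gene": [f"G{i:04d}" for i in range(n_bins)],
            "gc_fraction": rng.uniform(lo, hi, size=n_bins),
        }
    )
    return PanelDesign(bins)


def gc_bias_factor(gc: np.ndarray, strength: float) -> np.ndarray:
    """Smooth unimodal capture-efficiency curve peaking at GC = 0.5.

    ``strength`` 0 switches the bias off (factor identically 1); larger values
    depress coverage toward the GC extremes, mimicking library-prep bias.
    """
    if strength < 0:
        raise ValueError("gc_bias_strength must be >= 0")
    gc = np.asarray(gc, dtype=float)
    return np.exp(-strength * ((gc - 0.5) / 0.5) ** 2)


def _event_bin_mask(panel: PanelDesign, ev: CnvEvent) -> np.ndarray:
    b = panel.bins
    return ((b["chrom"] == ev.chrom) & (b["start"] < ev.end) & (b["end"] > ev.start)).to_numpy()


def generate_bin_counts(
    panel: PanelDesign,
    n_baseline: int,
    n_test: int,
    cnv_events: Sequence[CnvEvent | tuple] = (),
    gc_bias_strength: float = 0.0,
    depth_mean: float = 200.0,
    nb_dispersion: float | None = 50.0,
    seed: int = 0,
) -> tuple[BinCountSet, CohortTruth]:
    """Draw overdispersed per-bin read counts for a baseline cohort (no copy
    events) and test samples (with the planted ``cnv_events`` applied).

    The expected count of bin *b* in sample *s* is
    ``depth_mean * length_b / mean_length * gc_factor(gc_b) * multiplier``,
    with counts drawn negative-binomially (Poisson when ``nb_dispersion`` is
    None). Events whose coordinates cover no panel bin, or that name a
    baseline sample, are ignored with a warning and recorded in the truth.
    """
    if n_baseline < 2:
        raise ValueError("n_baseline must be >= 2 (a baseline cohort is required)")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    events = [ev if isinstance(ev, CnvEvent) else CnvEvent(*ev) for ev in cnv_events]
    baseline = [f"B{i:02d}" for i in range(n_baseline)]
    test = [f"T{i:02d}" for i in range(n_test)]
    truth = CohortTruth(seed=seed)
    truth.group_labels = {}

    lengths = panel.lengths.astype(float)
    base_mu = depth_mean * (lengths / lengths.mean()) * gc_bias_factor(
        panel.bins["gc_fraction"].to_numpy(), gc_bias_strength
    )

    mult = {s: np.ones(panel.n_bins) for s in baseline + test}
    for ev in events:
        if ev.sample in baseline or ev.sample not in mult:
            warnings.warn(f"CNV event on non-test sample {ev.sample!r} ignored")
            truth.ignored_events.append(ev)
            continue
        mask = _event_bin_mask(panel, ev)
        if not mask.any():
            warnings.warn(f"CNV event {ev} covers no panel bin; ignored")
            truth.ignored_events.append(ev)
            continue
        mult[ev.sample][mask] *= ev.multiplier
        truth.cnv_events.append(ev)

    cols = {}
    for s in baseline + test:
        mu = base_mu * mult[s]
        if nb_dispersion is None or not np.isfinite(nb_dispersion):
            cols[s] = rng.poisson(mu)
        else:
            p = nb_dispersion / (nb_dispersion + mu)
            cols[s] = rng.negative_binomial(nb_dispersion, p)
    counts = pd.DataFrame(cols)
    return BinCountSet(panel, counts, baseline, test), truth


_CONTAMINANT_RULES = ["synonymous", "intronic", "population_af", "low_support", "low_vaf", "strand_bias"]
_VAF_FLOOR = {"tumor": 0.05, "plasma": 0.01}


def generate_variants(
    panel: PanelDesign,
    samples: Sequence[str],
    mutation_rate_per_mb: float | Mapping[str, float] = 20.0,
    vaf_params: tuple[float, float] = (2.0, 8.0),
    contamination_fraction: float = 0.0,
    sample_type: str = "plasma",
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a somatic variant table plus rule-tagged contaminants.

    Each sample's true somatic count is ``round(rate * panel_bases / 1e6)``;
    VAFs follow a beta law conditioned to clear the sample-type VAF floor so
    that every clean record passes all filtering rules. A fraction of extra
    contaminant records is added, each violating exactly one filtering rule
    (the rule is recorded in the truth so per-rule filter behavior is
    attributable).
    """
    a, b = vaf_params
    if a <= 0 or b <= 0:
        raise ValueError("beta shape parameters must be positive")
    if not 0 <= contamination_fraction <= 1:
        raise ValueError("contamination_fraction must be in [0, 1]")
    if sample_type not in _VAF_FLOOR:
        raise ValueError(f"sample_type must be one of {sorted(_VAF_FLOOR)}")
    rng = np.random.default_rng(seed)
    bins = panel.bins
    floor = _VAF_FLOOR[sample_type]

    def rate_for(s: str) -> float:
        r = mutation_rate_per_mb[s] if isinstance(mutation_rate_per_mb, Mapping) else mutation_rate_per_mb
        if r < 0:
            raise ValueError("mutation rate must be non-negative")
        return float(r)

    def clean_vaf() -> float:
        # rejection sampling keeps the beta shape above the filtering floor
        for _ in range(1000):
            v = float(rng.beta(a, b))
            if v >= max(floor, 0.02):
                return v
        return max(floor, 0.02)

    def base_record(s: str) -> dict:
        i = int(rng.integers(0, len(bins)))
        row = bins.iloc[i]
        return {
            "sample": s,
            "sample_type": sample_type,
            "chrom": row["chrom"],
            "pos": int(row["start"]) + int(rng.integers(0, row["end"] - row["start"])) + 1,
            "ref": str(rng.choice(list("ACGT"))),
            "alt": str(rng.choice(list("ACGT"))),
            "gene": row["gene"],
            "functional_class": "nonsynonymous",
            "region_class": "exonic",
            "vaf": clean_vaf(),
            "support_reads": int(rng.integers(5, 400)),
            "population_af": 0.0,
            "strand_bias": False,
        }

    records, cont_records = [], []
    truth = CohortTruth(seed=seed)
    for s in samples:
        n_true = round(rate_for(s) * panel.exonic_base_total / 1e6)
        truth.true_mutation_counts[s] = n_true
        for _ in range(n_true):
            records.append(base_record(s))
        n_cont = round(contamination_fraction * n_true)
        for j in range(n_cont):
            rec = base_record(s)
            rule = _CONTAMINANT_RULES[j % len(_CONTAMINANT_RULES)]
            if rule == "synonymous":
                rec["functional_class"] = "synonymous"
            elif rule == "intronic":
                rec["region_class"] = "intronic"
            elif rule == "population_af":
                rec["population_af"] = float(rng.uniform(0.002, 0.05))
            elif rule == "low_support":
                rec["support_reads"] = int(rng.integers(0, 5))
            elif rule == "low_vaf":
                rec["vaf"] = float(rng.uniform(0.001, floor * 0.99))
            elif rule == "strand_bias":
                rec["strand_bias"] = True
            cont_records.append({**rec, "planted_rule": rule})
            records.append(rec)

    columns = [
        "sample", "sample_type", "chrom", "pos", "ref", "alt", "gene",
        "functional_class", "region_class", "vaf", "support_reads",
        "population_af", "strand_bias",
    ]
    table = pd.DataFrame(records, columns=columns)
    truth.contaminants = pd.DataFrame(cont_records, columns=columns + ["planted_rule"])
    return table, truth


def generate_cnv_states(
    genes: Sequence[str],
    samples: Sequence[str],
    group_labels: Mapping[str, str] | None = None,
    signal_genes: Sequence[str] = (),
    gain_group: str = "better",
    effect: float = 1.0,
    background_alteration_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x sample integer copy-number states in {-2..2}.

    ``signal_genes`` are shifted toward gain in ``gain_group`` samples with
    probability proportional to ``effect`` (capped at 1); all other entries are
    sparse random background alterations.
    """
    rng = np.random.default_rng(seed)
    states = pd.DataFrame(0, index=list(genes), columns=list(samples), dtype=int)
    for g in genes:
        for s in samples:
            if rng.random() < background_alteration_rate:
                states.loc[g, s] = int(rng.choice([-2, -1, 1, 2], p=[0.1, 0.4, 0.4, 0.1]))
    if group_labels is not None:
        p_gain = min(1.0, 0.5 * effect)
        for g in signal_genes:
            for s in samples:
                if group_labels[s] == gain_group and rng.random() < p_gain:
                    states.loc[g, s] = int(rng.choice([1, 2], p=[0.7, 0.3]))
    return states


def generate_expression_survival(
    samples: Sequence[str],
    gene_cnv_states: pd.DataFrame,
    group_labels: Mapping[str, str],
    dosage_slope: float = 1.0,
    noise_sd: float = 0.5,
    baseline_hazard: float = 0.1,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
    baseline_expression: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Dosage-coupled expression plus exponential survival with a group hazard
    ratio.

    expression(g, s) = per-gene baseline + dosage_slope * state(g, s) + N(0, noise_sd);
    survival times are exponential with hazard ``baseline_hazard`` for the
    "better" group and ``baseline_hazard * hazard_ratio`` for the "poor" group,
    independently censored so that a fraction ``censor_rate`` of records is
    censored in expectation (censor_rate 0 means every record is an event).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if baseline_hazard <= 0 or hazard_ratio <= 0:
        raise ValueError("hazards must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    samples = list(samples)
    if set(samples) - set(gene_cnv_states.columns):
        raise ValueError("every sample must have a CNV state column")
    rng = np.random.default_rng(seed)

    genes = gene_cnv_states.index
    gene_base = baseline_expression + rng.normal(0, 1.0, size=len(genes))
    noise = rng.normal(0, noise_sd, size=(len(genes), len(samples))) if noise_sd > 0 else 0.0
    expr = (
        gene_base[:, None]
        + dosage_slope * gene_cnv_states.loc[genes, samples].to_numpy(dtype=float)
        + noise
    )
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    rows = []
    for s in samples:
        lam = baseline_hazard * (hazard_ratio if group_labels[s] == "poor" else 1.0)
        t_event = rng.exponential(1.0 / lam)
        if censor_rate > 0:
            mu = lam * censor_rate / (1 - censor_rate)
            t_cens = rng.exponential(1.0 / mu)
        else:
            t_cens = np.inf
        rows.append(
            {
                "sample": s,
                "time": float(min(t_event, t_cens)),
                "event": int(t_event <= t_cens),
                "group": group_labels[s],
            }
        )
    clinical = pd.DataFrame(rows)
    truth = CohortTruth(
        seed=seed,
        dosage_slope=dosage_slope,
        hazard_ratio=hazard_ratio,
        group_labels=dict(group_labels),
    )
    return expression, clinical, truth
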
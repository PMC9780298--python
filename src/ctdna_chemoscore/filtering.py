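"""Rule-based somatic-mutation filtering for panel variant tables.

Three elimination rules are applied in sequence to every call:

R1_annotation    synonymous SNVs, or calls in intergenic/intronic regions
R2_population_af population allele frequency >= 0.002 (ExAC/gnomAD, collapsed
                 to the maximum of available values)
R3_quality       strand bias, support reads < 5, or VAF below the sample-type
                 floor (< 0.05 tumor, < 0.01 plasma; equality survives)

Each removed call is attributed to the FIRST rule it violates, so per-rule
removal counts are well defined. A missing population AF is treated as 0
(absent from the population databases means presumed rare).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantCall",
    "FilterReport",
    "filter_somatic",
    "filter_table",
    "read_variant_table",
    "write_variant_table",
    "TSV_COLUMNS",
]

TSV_COLUMNS = [
    "sample",
    "sample_type",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "functional_class",
    "region_class",
    "vaf",
    "support_reads",
    "population_af",
    "strand_bias",
]

SAMPLE_TYPES = {"tumor", "plasma"}
VAF_FLOOR = {"tumor": 0.05, "plasma": 0.01}
POPULATION_AF_CUTOFF = 0.002
MIN_SUPPORT_READS = 5
R1_REGIONS = {"intergenic", "intronic"}

RULE_IDS = ("R1_annotation", "R2_population_af", "R3_quality")


@dataclass(frozen=True)
class VariantCall:
    sample: str
    sample_type: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: str
    region_class: str
    vaf: float
    support_reads: int
    population_af: float = 0.0
    strand_bias: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.vaf <= 1:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf} ({self._locus()})")
        if not 0 <= self.population_af <= 1:
            raise ValueError(f"population_af must be in [0, 1] ({self._locus()})")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 ({self._locus()})")
        if self.support_reads < 0:
            raise ValueError(f"support_reads must be >= 0 ({self._locus()})")

    def _locus(self) -> str:
        return f"{self.sample}:{self.chrom}:{self.pos}"


@dataclass
class FilterReport:
    retained: list[VariantCall]
    removed: list[tuple[VariantCall, str]]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {r: 0 for r in RULE_IDS}
            for _, rule in self.removed:
                self.counts[rule] += 1

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.removed)

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": len(self.retained),
            "n_removed": len(self.removed),
            "removed_per_rule": dict(self.counts),
        }


def _violated_rule(call: VariantCall) -> str | None:
    if call.sample_type not in SAMPLE_TYPES:
        raise ValueError(
            f"unknown sample_type {call.sample_type!r} for record {call._locus()}"
        )
    if call.functional_class == "synonymous" or call.region_class in R1_REGIONS:
        return "R1_annotation"
    if call.population_af >= POPULATION_AF_CUTOFF:
        return "R2_population_af"
    if (
        call.strand_bias
        or call.support_reads < MIN_SUPPORT_READS
        or call.vaf < VAF_FLOOR[call.sample_type]
    ):
        return "R3_quality"
    return None


def filter_somatic(calls: Iterable[VariantCall]) -> FilterReport:
    """Apply the three elimination rules; tag each removal with the first
    rule it violates. Idempotent on its own retained set."""
    retained: list[VariantCall] = []
    removed: list[tuple[VariantCall, str]] = []
    for call in calls:
        rule = _violated_rule(call)
        if rule is None:
            retained.append(call)
        else:
            removed.append((call, rule))
    return FilterReport(retained=retained, removed=removed)


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=TSV_COLUMNS)
    return pd.DataFrame([{f.name: getattr(c, f.name) for f in dc_fields(c)} for c in calls])[TSV_COLUMNS]


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing mandatory columns: {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            calls.append(
                VariantCall(
                    sample=str(row.sample),
                    sample_type=str(row.sample_type),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    functional_class=str(row.functional_class),
                    region_class=str(row.region_class),
                    vaf=float(row.vaf),
                    support_reads=int(row.support_reads),
                    population_af=0.0 if pd.isna(row.population_af) else float(row.population_af),
                    strand_bias=_parse_bool(row.strand_bias),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed variant record at data row {i + 1}: {exc}") from exc
    return calls


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes", "t"}
    return bool(x)


def filter_table(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Filter a variant DataFrame in the TSV dialect; returns the retained
    rows (same schema) and the per-rule report."""
    report = filter_somatic(frame_to_calls(df))
    return calls_to_frame(report.retained), report


def read_variant_table(path, dialect: str = "tsv") -> list[VariantCall]:
    """Read variants from the TSV dialect or (read-only) from a minimal VCF.

    VCF mapping: one record per call with INFO keys SAMPLE, STYPE, GENE,
    FCLASS, RCLASS, VAF, SR, PAF (VAF/PAF typed as String so values
    round-trip exactly) and the flag SBIAS for strand bias.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        return frame_to_calls(df)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls = []
    for i, v in enumerate(VCF(str(path)), start=1):
        info = v.INFO
        try:
            calls.append(
                VariantCall(
                    sample=info["SAMPLE"],
                    sample_type=info["STYPE"],
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=v.ALT[0] if v.ALT else ".",
                    gene=info.get("GENE") or "",
                    functional_class=info.get("FCLASS") or "other",
                    region_class=info.get("RCLASS") or "other",
                    vaf=float(info["VAF"]),
                    support_reads=int(info["SR"]),
                    population_af=float(info.get("PAF") or 0.0),
                    strand_bias=bool(info.get("SBIAS")),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    return calls


def write_variant_table(calls: Sequence[VariantCall] | pd.DataFrame, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect == "vcf":
        if isinstance(calls, pd.DataFrame):
            calls = frame_to_calls(calls)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                "##INFO=<ID=SAMPLE,Number=1,Type=String,Description=\"Sample label\">\n"
                "##INFO=<ID=STYPE,Number=1,Type=String,Description=\"tumor or plasma\">\n"
                "##INFO=<ID=GENE,Number=1,Type=String,Description=\"Gene\">\n"
                "##INFO=<ID=FCLASS,Number=1,Type=String,Description=\"Functional class\">\n"
                "##INFO=<ID=RCLASS,Number=1,Type=String,Description=\"Region class\">\n"
                "##INFO=<ID=VAF,Number=1,Type=String,Description=\"Variant allele frequency\">\n"
                "##INFO=<ID=SR,Number=1,Type=Integer,Description=\"Support reads\">\n"
                "##INFO=<ID=PAF,Number=1,Type=String,Description=\"Population allele frequency\">\n"
                "##INFO=<ID=SBIAS,Number=0,Type=Flag,Description=\"Strand bias\">\n"
            )
            for chrom in sorted({c.chrom for c in calls}):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for c in calls:
                info = (
                    f"SAMPLE={c.sample};STYPE={c.sample_type};GENE={c.gene};"
                    f"FCLASS={c.functional_class};RCLASS={c.region_class};"
                    f"VAF={c.vaf!r};SR={c.support_reads};PAF={c.population_af!r}"
                )
                if c.strand_bias:
                    info += ";SBIAS"
                fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t{info}\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}")
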
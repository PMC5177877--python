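"""Readers and writers for the pipeline's standard formats.

Formats handled here:

* phased VCF 4.2 (di-allelic InDel records) plus a side-car sample-map TSV
  (sample id, population) — VCF has no standard population field;
* panel-definition tables (``marker_id  rsid  chrom  pos  alleles``) and
  marker amplicon-size tables;
* haplotype-frequency "workbooks": one CSV per marker in a directory, with
  populations as rows and haplotype keys as columns — the training-set
  format consumed by the naive-Bayes classifier.

All coordinates at these interfaces are 1-based. Readers reject files that
violate type invariants with errors naming the offending record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cohort import MISSING, PhasedCohort
from .panel import InDelVariant, MultiInDelMarker, PanelDefinition, allele_length

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Haplotype frequency tables
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeFrequencyTable:
    """Per-marker haplotype relative frequencies by population.

    One DataFrame per marker: index = population names, columns = haplotype
    keys. Keys are either CE amplicon sizes (e.g. ``"122"``) or allele-state
    strings (e.g. ``"01"``) — a single namespace per table, never mixed.
    Every row sums to 1 (within 1e-9); zero-frequency columns are kept so
    the haplotype alphabet is stable across populations.
    """

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker_id, df in self.tables.items():
            self.tables[marker_id] = _validate_frequency_frame(marker_id, df)

    def __iter__(self):
        return iter(self.tables.items())

    def __len__(self) -> int:
        return len(self.tables)

    def __getitem__(self, marker_id: str) -> pd.DataFrame:
        return self.tables[str(marker_id)]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.tables)

    @property
    def populations(self) -> list[str]:
        pops: list[str] = []
        for df in self.tables.values():
            for p in df.index:
                if p not in pops:
                    pops.append(p)
        return pops

    def equals(self, other: "HaplotypeFrequencyTable", tol: float = 1e-12) -> bool:
        if set(self.tables) != set(other.tables):
            return False
        for mid, df in self.tables.items():
            odf = other.tables[mid]
            if list(df.index) != list(odf.index) or list(df.columns) != list(odf.columns):
                return False
            if not np.allclose(df.to_numpy(), odf.to_numpy(), atol=tol):
                return False
        return True


def _validate_frequency_frame(marker_id: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    vals = df.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError(f"marker {marker_id}: frequencies must lie in [0, 1]")
    sums = vals.sum(axis=1)
    for pop, s in zip(df.index, sums):
        if abs(s - 1.0) > ROW_SUM_TOL:
            raise ValueError(
                f"marker {marker_id}, population {pop}: frequencies sum to {s!r}, not 1"
            )
    return df


def write_frequency_workbook(tables: HaplotypeFrequencyTable, path: str | Path) -> None:
    """One ``marker_<id>.csv`` per marker, populations as rows."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for marker_id, df in tables:
        out = df.copy()
        out.insert(0, "population", out.index)
        out.to_csv(path / f"marker_{marker_id}.csv", index=False)


def read_frequency_workbook(path: str | Path) -> HaplotypeFrequencyTable:
    """Exact inverse of :func:`write_frequency_workbook`."""
    path = Path(path)
    files = sorted(path.glob("marker_*.csv"))
    if not files:
        raise FileNotFoundError(f"no marker_*.csv files under {path}")
    tables: dict[str, pd.DataFrame] = {}
    for f in files:
        marker_id = f.stem.removeprefix("marker_")
        df = pd.read_csv(f, dtype={"population": str})
        df = df.set_index("population")
        df.index.name = None
        tables[marker_id] = df
    return HaplotypeFrequencyTable(tables)


# ---------------------------------------------------------------------------
# Panel tables
# ---------------------------------------------------------------------------

def _parse_allele_pair(text: str, row_desc: str) -> tuple[str, str]:
    parts = str(text).strip().split("/")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"{row_desc}: cannot parse allele pair {text!r}")
    a, b = parts
    if allele_length(a) == allele_length(b):
        raise ValueError(f"{row_desc}: alleles {text!r} have equal length; not an InDel")
    short, long_ = sorted(parts, key=allele_length)
    return short, long_


def read_panel_table(path: str | Path) -> PanelDefinition:
    """Parse a panel membership table into a PanelDefinition.

    Expected columns: marker_id, rsid, chrom, pos, alleles (a slash-separated
    pair, ``-`` for the absent allele). Consecutive rows sharing a marker_id
    form one marker; positions within a marker must be strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"marker_id", "rsid", "chrom", "pos", "alleles"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    markers: list[MultiInDelMarker] = []
    current_id: str | None = None
    current: list[InDelVariant] = []

    def flush() -> None:
        if current_id is not None:
            markers.append(MultiInDelMarker(marker_id=current_id, loci=tuple(current)))

    for _, row in df.iterrows():
        desc = f"{path}, rsid {row['rsid']}"
        short, long_ = _parse_allele_pair(row["alleles"], desc)
        v = InDelVariant(
            rsid=str(row["rsid"]),
            chrom=str(row["chrom"]),
            position=int(row["pos"]),
            short_allele=short,
            long_allele=long_,
        )
        if str(row["marker_id"]) != current_id:
            flush()
            current_id = str(row["marker_id"])
            current = [v]
        else:
            if v.position <= current[-1].position:
                raise ValueError(
                    f"{desc}: position {v.position} not increasing within marker {current_id}"
                )
            current.append(v)
    flush()
    return PanelDefinition(markers=markers, provenance=str(path))


def read_amplicon_table(path: str | Path) -> dict[str, int]:
    """marker_id -> assay amplicon size (bp)."""
    df = pd.read_csv(Path(path), sep=None, engine="python", dtype=str)
    if missing := {"marker_id", "amplicon_size"} - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {str(r["marker_id"]): int(r["amplicon_size"]) for _, r in df.iterrows()}


def bundled_panel() -> PanelDefinition:
    """The 12-marker multi-InDel panel shipped with the package."""
    with resources.as_file(resources.files("multindel.data") / "panel_members.tsv") as p:
        return read_panel_table(p)


def bundled_amplicon_sizes() -> dict[str, int]:
    """Assay amplicon sizes (bp) for the bundled panel."""
    with resources.as_file(resources.files("multindel.data") / "panel_amplicons.tsv") as p:
        return read_amplicon_table(p)


# ---------------------------------------------------------------------------
# Sample maps and VCF
# ---------------------------------------------------------------------------

def write_sample_map(cohort: PhasedCohort, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": cohort.sample_ids, "population": cohort.populations}
    ).to_csv(Path(path), sep="\t", index=False)


def read_sample_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if missing := {"sample_id", "population"} - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["sample_id"], df["population"]))


def read_phased_vcf(
    vcf_path: str | Path,
    sample_map_path: str | Path,
    on_unphased: str = "error",
) -> PhasedCohort:
    """Load a phased VCF of di-allelic InDels into a PhasedCohort.

    Only di-allelic records whose REF/ALT differ in length are kept (SNPs
    and multi-allelic records are skipped with a logged warning). Allele
    states are normalized to 0 = short allele, 1 = long allele regardless
    of which of REF/ALT is shorter.

    Unphased heterozygous genotypes are rejected (``on_unphased="error"``,
    the default: haplotype counting is only exact with phase) or recorded
    as missing for that sample/locus (``on_unphased="missing"``). Missing
    genotypes are recorded as missing, never imputed.
    """
    if on_unphased not in ("error", "missing"):
        raise ValueError("on_unphased must be 'error' or 'missing'")
    sample_map = read_sample_map(sample_map_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in sample_map:
            raise ValueError(f"sample {s} missing from sample map {sample_map_path}")

    loci: list[InDelVariant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", rec.CHROM, rec.POS)
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) == len(alt):
            continue  # SNP/MNP: not an InDel
        short_raw, long_raw = sorted([ref, alt], key=len)
        # strip the shared anchor prefix so alleles match panel-table style
        k = 0
        while k < len(short_raw) and short_raw[k] == long_raw[k]:
            k += 1
        short = short_raw[k:] or "-"
        long_ = long_raw[k:]
        ref_state = 0 if len(ref) < len(alt) else 1  # state of GT allele 0
        loci.append(
            InDelVariant(
                rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                position=int(rec.POS),
                short_allele=short,
                long_allele=long_,
            )
        )
        col = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a0, a1, phased = gt[0], gt[1], bool(gt[2])
            if a0 < 0 or a1 < 0:
                continue  # missing stays MISSING
            if not phased and a0 != a1:
                if on_unphased == "error":
                    raise ValueError(
                        f"unphased heterozygote for sample {samples[i]} at "
                        f"{rec.CHROM}:{rec.POS}; rerun with on_unphased='missing' to drop"
                    )
                logger.warning(
                    "dropping unphased heterozygote %s at %s:%s", samples[i], rec.CHROM, rec.POS
                )
                continue
            col[i, 0] = a0 if ref_state == 0 else 1 - a0
            col[i, 1] = a1 if ref_state == 0 else 1 - a1
        columns.append(col)

    if not loci:
        raise ValueError(f"{vcf_path}: no di-allelic InDel records found")
    haplotypes = np.stack(columns, axis=-1) if columns else np.empty((len(samples), 2, 0))
    return PhasedCohort(
        sample_ids=samples,
        populations=[sample_map[s] for s in samples],
        loci=loci,
        haplotypes=haplotypes,
    )


def write_panel_table(panel: PanelDefinition, path: str | Path) -> None:
    """Write a panel back to the membership-table format read_panel_table expects."""
    rows = []
    for m in panel:
        for v in m.loci:
            rows.append(
                {
                    "marker_id": m.marker_id,
                    "rsid": v.rsid,
                    "chrom": v.chrom,
                    "pos": v.position,
                    "alleles": f"{v.short_allele}/{v.long_allele}",
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> None:
    """0-based half-open intervals spanning each marker's member loci."""
    with open(path, "w") as fh:
        for m in panel:
            start = m.loci[0].position - 1
            end = m.loci[-1].position - 1 + max(1, allele_length(m.loci[-1].short_allele))
            fh.write(f"{m.chrom}\t{start}\t{end}\t{m.marker_id}\n")
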
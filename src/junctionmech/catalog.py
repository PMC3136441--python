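"""Machine-readable cohort catalog of the 44 subjects and its aggregates.

The bundled table transcribes, one row per subject, the rearrangement class
(terminal deletion, interstitial deletion, ring 22, derivative chromosome),
deletion size, repair mechanism where the junction was cloned, parental
origin, and mosaic percentage.  Sizes printed with a leading "~" are stored
with an ``approximate`` flag and excluded from min/max summaries.
Derivative chromosomes were inherited from balanced-translocation carrier
parents and are excluded from the de novo parental-origin table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Iterable

import pandas as pd

CLASSES = {
    "Terminal deletion": "terminal_deletion",
    "Interstitial deletion": "interstitial_deletion",
    "Ring 22": "ring22",
    "Derivative chromosome": "derivative",
}
MECHANISMS = {
    "Telomere healing": "telomere_healing",
    "Telomere capture": "telomere_capture",
    "NHEJ": "NHEJ",
    "FoSTeS": "FoSTeS",
    "": "unknown",
}
ORIGINS = {"Pat": "paternal", "Mat": "maternal", "U": "unknown"}
ASCERTAINMENT = {"K", "Tel-FISH", "Tel-MLPA", "aCGH"}


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    ascertainment: tuple[str, ...]
    karyotype: str
    rearrangement_class: str
    del_size_bp: int | None
    size_approximate: bool
    associated_imbalance: str | None
    repair_mechanism: str
    parental_origin: str
    mosaic_percent: int | None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ascertainment"] = list(self.ascertainment)
        return d


def _parse_size(text: str) -> tuple[int | None, bool]:
    text = text.strip()
    if not text:
        return None, False
    approx = text.startswith(("~", "≈", "∼"))
    text = text.lstrip("~≈∼").strip()
    value, unit = text.rsplit(" ", 1)
    value = value.replace(",", "")
    if unit == "Mb":
        return int(round(float(value) * 1_000_000)), approx
    if unit == "bp":
        return int(value), approx
    raise ValueError(f"unparseable size {text!r}")


def load_catalog(path=None) -> list[PatientRecord]:
    """Load and validate the cohort table (the bundled one by default)."""
    if path is None:
        with resources.files("junctionmech.data").joinpath("table1_cohort.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.fillna("")
    records: list[PatientRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            asc = tuple(a.strip() for a in row.ascertainment.split(","))
            if not set(asc) <= ASCERTAINMENT:
                raise ValueError(f"unknown ascertainment {row.ascertainment!r}")
            if row.sex not in ("M", "F"):
                raise ValueError(f"unknown sex {row.sex!r}")
            size_bp, approx = _parse_size(row.del_size)
            if size_bp is not None and size_bp <= 0:
                raise ValueError("deletion size must be positive")
            records.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    sex=row.sex,
                    ascertainment=asc,
                    karyotype=row.karyotype,
                    rearrangement_class=CLASSES[row.rearrangement_class],
                    del_size_bp=size_bp,
                    size_approximate=approx,
                    associated_imbalance=row.associated_imbalance or None,
                    repair_mechanism=MECHANISMS[row.repair_mechanism],
                    parental_origin=ORIGINS[row.parental_origin],
                    mosaic_percent=int(row.mosaic_percent) if row.mosaic_percent else None,
                )
            )
        except (KeyError, ValueError, AttributeError) as exc:
            raise ValueError(f"unparseable catalog row {row_no}: {exc}") from exc
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in catalog")
    if len(records) != 44:
        raise ValueError(f"catalog must contain exactly 44 records, found {len(records)}")
    return records


def class_counts(records: Iterable[PatientRecord]) -> dict[str, int]:
    counts = {cls: 0 for cls in CLASSES.values()}
    for r in records:
        counts[r.rearrangement_class] += 1
    return counts


def parental_origin_counts(records: Iterable[PatientRecord], classes: Iterable[str]) -> tuple[int, int, int, int]:
    """(n_informative, n_paternal, n_maternal, pct_paternal) for the given
    de novo classes; percentages are rounded to integers."""
    classes = set(classes)
    if "derivative" in classes:
        raise ValueError("derivative chromosomes are inherited, not de novo")
    pat = mat = 0
    for r in records:
        if r.rearrangement_class in classes:
            if r.parental_origin == "paternal":
                pat += 1
            elif r.parental_origin == "maternal":
                mat += 1
    informative = pat + mat
    pct = round(100 * pat / informative) if informative else 0
    return informative, pat, mat, pct


def parental_origin_table(records: Iterable[PatientRecord]) -> dict[str, tuple[int, int, int, int]]:
    """The de novo parental-origin table: simple del(22) (terminal +
    interstitial), ring 22, and total; derivative chromosomes excluded."""
    records = list(records)
    return {
        "del22": parental_origin_counts(records, ["terminal_deletion", "interstitial_deletion"]),
        "ring22": parental_origin_counts(records, ["ring22"]),
        "total": parental_origin_counts(
            records, ["terminal_deletion", "interstitial_deletion", "ring22"]
        ),
    }


def size_summary(records: Iterable[PatientRecord], rearrangement_class: str) -> tuple[int, int, int]:
    """(min_bp, max_bp, n) for one class; approximate sizes excluded from
    min/max but counted in n."""
    if rearrangement_class not in CLASSES.values():
        raise ValueError(f"unknown rearrangement class {rearrangement_class!r}")
    in_class = [r for r in records if r.rearrangement_class == rearrangement_class]
    exact = [r.del_size_bp for r in in_class if r.del_size_bp is not None and not r.size_approximate]
    if not exact:
        raise ValueError(f"no exact sizes for class {rearrangement_class!r}")
    return min(exact), max(exact), len(in_class)


def cohort_report(records: Iterable[PatientRecord]) -> dict:
    """All printed aggregates in one JSON-serializable report."""
    records = list(records)
    counts = class_counts(records)
    n = len(records)
    origin = parental_origin_table(records)
    report = {
        "n_records": n,
        "class_counts": counts,
        "class_percent": {cls: round(100 * c / n, 1) for cls, c in counts.items()},
        "parental_origin": {
            key: {
                "informative": v[0],
                "paternal": v[1],
                "maternal": v[2],
                "paternal_pct": v[3],
            }
            for key, v in origin.items()
        },
        "parental_origin_by_class": {
            cls: parental_origin_counts(records, [cls])
            for cls in ("terminal_deletion", "interstitial_deletion", "ring22")
        },
        "size_summary": {
            cls: size_summary(records, cls)
            for cls in ("terminal_deletion", "interstitial_deletion", "ring22")
        },
        "mechanism_counts": {
            mech: sum(r.repair_mechanism == mech for r in records)
            for mech in sorted(set(MECHANISMS.values()))
        },
    }
    _validate_report(report)
    return report


def _validate_report(report: dict) -> None:
    required = {
        "n_records",
        "class_counts",
        "class_percent",
        "parental_origin",
        "parental_origin_by_class",
        "size_summary",
        "mechanism_counts",
    }
    missing = required - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if sum(report["class_counts"].values()) != report["n_records"]:
        raise ValueError("class counts do not sum to the record total")


def report_to_text(report: dict) -> str:
    lines = [f"cohort: {report['n_records']} subjects"]
    for cls, c in report["class_counts"].items():
        lines.append(f"  {cls}: {c} ({report['class_percent'][cls]}%)")
    for key, v in report["parental_origin"].items():
        lines.append(
            f"  de novo {key}: {v['paternal']}/{v['informative']} paternal ({v['paternal_pct']}%)"
        )
    for cls, (mn, mx, cnt) in report["size_summary"].items():
        lines.append(f"  {cls} sizes: {mn:,}-{mx:,} bp (n={cnt})")
    return "\n".join(lines) + "\n"


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
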
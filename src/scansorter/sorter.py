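"""Sort predicted scans into a BIDS tree or a user-defined DICOM layout,
plus the metadata-heuristic baseline classifier.

BIDS mapping (anat/dwi are core BIDS; DSC perfusion has no finalized core
home, so it goes under ``perf/`` with suffix ``_dsc`` as a documented
extension; derived parametric maps go to ``derivatives/scansorter/``,
which is the idiomatic place for non-raw data):

====================  =========================================
scan type             destination
====================  =========================================
T1w                   anat/sub-X[_ses-Y]_T1w.nii.gz
T1wC                  anat/sub-X[_ses-Y]_ce-gd_T1w.nii.gz
T2w                   anat/..._T2w.nii.gz
PDw                   anat/..._PDw.nii.gz
T2w-FLAIR             anat/..._FLAIR.nii.gz
DWI                   dwi/..._dwi.nii.gz
PWI-DSC               perf/..._dsc.nii.gz
derived               derivatives/scansorter/sub-X/...
====================  =========================================

Duplicate scans of one type within a session get ``run-01``, ``run-02``
... in stable (sorted scan_id) order.  Plans are inspectable before
execution; execution is idempotent (re-running skips byte-identical
destinations) and aborts before touching anything if a destination would
be overwritten with different content.
"""

from __future__ import annotations

import hashlib
import json
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .dicom_io import assemble_volume, scan_directory, write_nifti
from .types import ScanPrediction, SeriesMetadata

_BIDS_SUFFIX = {
    "T1w": ("anat", "T1w", None),
    "T1wC": ("anat", "T1w", "ce-gd"),
    "T2w": ("anat", "T2w", None),
    "PDw": ("anat", "PDw", None),
    "T2w-FLAIR": ("anat", "FLAIR", None),
    "DWI": ("dwi", "dwi", None),
    "PWI-DSC": ("perf", "dsc", None),
}

#: filename grammar for the BIDS names this package emits
BIDS_NAME_RE = re.compile(
    r"^sub-[A-Za-z0-9]+(_ses-[A-Za-z0-9]+)?(_ce-[A-Za-z0-9]+)?"
    r"(_run-[0-9]+)?_(T1w|T2w|PDw|FLAIR|dwi|dsc)\.nii(\.gz)?$"
)

TEMPLATE_PLACEHOLDERS = {"subject", "session", "scan_type", "orientation", "run"}


@dataclass
class PlanEntry:
    scan_id: str
    sources: list[Path]
    destination: Path
    action: str  # "copy" | "move" | "convert"
    scan_class: str
    orientation: str = ""
    run: int = 1


@dataclass
class SortPlan:
    root: Path
    entries: list[PlanEntry] = field(default_factory=list)
    extra_files: dict[str, str] = field(default_factory=dict)  # relpath -> content

    def __post_init__(self) -> None:
        dests = [e.destination for e in self.entries]
        if len(set(dests)) != len(dests):
            dupes = sorted({str(d) for d in dests if dests.count(d) > 1})
            raise ValueError(f"sort plan has colliding destinations: {dupes}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records([
            {"scan_id": e.scan_id, "destination": str(e.destination),
             "action": e.action, "class": e.scan_class, "run": e.run,
             "n_sources": len(e.sources)}
            for e in self.entries
        ])


def _zero_pad(label: str) -> str:
    return f"{int(label):03d}" if label.isdigit() else label


def _clean(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]", "", label)


def _assign_runs(items: list[tuple]) -> dict[str, tuple[int, bool]]:
    """scan_id -> (run index, needs_run_suffix) within (subject, session, class)."""
    groups: dict[tuple, list[str]] = {}
    for scan_id, key in items:
        groups.setdefault(key, []).append(scan_id)
    out = {}
    for key, scan_ids in groups.items():
        scan_ids = sorted(scan_ids)  # stable run assignment
        need = len(scan_ids) > 1
        for run, sid in enumerate(scan_ids, start=1):
            out[sid] = (run, need)
    return out


def plan_bids(predictions: Sequence[ScanPrediction], manifest: pd.DataFrame,
              out_root: Path | str, source_column: str = "nifti_path") -> SortPlan:
    """Build a BIDS sorting plan for NIfTI outputs.

    ``manifest`` needs columns ``scan_id``, ``subject``, ``session`` and a
    source column: either a NIfTI file path or a DICOM series directory
    (which execution converts to NIfTI).
    """
    out_root = Path(out_root)
    man = manifest.set_index(manifest["scan_id"].astype(str))
    missing = [p.scan_id for p in predictions if p.scan_id not in man.index]
    if missing:
        raise ValueError(f"manifest lacks rows for scans: {missing}")

    keys = []
    for p in predictions:
        row = man.loc[p.scan_id]
        if not str(row["subject"]).strip():
            raise ValueError(f"unresolvable subject id for scan {p.scan_id}")
        keys.append((p.scan_id, (str(row["subject"]), str(row["session"]),
                                 p.predicted_class)))
    runs = _assign_runs(keys)

    entries = []
    for p in predictions:
        row = man.loc[p.scan_id]
        sub = "sub-" + _clean(_zero_pad(str(row["subject"])))
        ses = str(row["session"]).strip()
        ses_label = ("ses-" + _clean(_zero_pad(ses))) if ses else ""
        run, need_run = runs[p.scan_id]
        source = Path(str(row[source_column]))
        action = "convert" if source.is_dir() else "copy"

        if p.predicted_class == "derived":
            rel = Path("derivatives") / "scansorter" / sub
            if ses_label:
                rel = rel / ses_label
            name_parts = [sub] + ([ses_label] if ses_label else [])
            if need_run:
                name_parts.append(f"run-{run:02d}")
            name = "_".join(name_parts) + "_desc-derived_map.nii.gz"
            dest = out_root / rel / name
        else:
            datatype, suffix, ce = _BIDS_SUFFIX[p.predicted_class]
            rel = Path(sub) / (ses_label or "") / datatype
            name_parts = [sub] + ([ses_label] if ses_label else [])
            if ce:
                name_parts.append(ce.replace("ce-", "ce-"))
            if need_run:
                name_parts.append(f"run-{run:02d}")
            name = "_".join(name_parts) + f"_{suffix}.nii.gz"
            dest = out_root / rel / name

        entries.append(PlanEntry(
            scan_id=p.scan_id, sources=[source], destination=dest,
            action=action, scan_class=p.predicted_class,
            orientation=p.orientation or "", run=run,
        ))

    dataset_description = json.dumps({
        "Name": "scansorter output",
        "BIDSVersion": "1.8.0",
        "GeneratedBy": [{"Name": "scansorter"}],
    }, indent=2)
    return SortPlan(root=out_root, entries=entries,
                    extra_files={"dataset_description.json": dataset_description})


def plan_custom(predictions: Sequence[ScanPrediction], manifest: pd.DataFrame,
                template: str, out_root: Path | str,
                source_column: str = "path", action: str = "copy") -> SortPlan:
    """Build a DICOM sorting plan from a path template.

    The template may use ``{subject}``, ``{session}``, ``{scan_type}``,
    ``{orientation}`` and ``{run}``; each scan's DICOM files are placed,
    byte-identical, into its formatted destination directory.
    """
    used = set(re.findall(r"{([^{}]*)}", template))
    unknown = used - TEMPLATE_PLACEHOLDERS
    if unknown:
        raise ValueError(
            f"unknown template placeholder(s): {sorted(unknown)}; "
            f"valid: {sorted(TEMPLATE_PLACEHOLDERS)}")
    out_root = Path(out_root)
    man = manifest.set_index(manifest["scan_id"].astype(str))

    keys = []
    for p in predictions:
        row = man.loc[p.scan_id]
        keys.append((p.scan_id, (str(row["subject"]), str(row["session"]),
                                 p.predicted_class)))
    runs = _assign_runs(keys)

    entries = []
    for p in predictions:
        row = man.loc[p.scan_id]
        run, _ = runs[p.scan_id]
        rel = template.format(
            subject=str(row["subject"]), session=str(row["session"]),
            scan_type=p.predicted_class, orientation=p.orientation or "unknown",
            run=f"{run:02d}",
        )
        src_dir = Path(str(row[source_column]))
        sources = sorted(pth for pth in src_dir.rglob("*") if pth.is_file()) \
            if src_dir.is_dir() else [src_dir]
        for src in sources:
            entries.append(PlanEntry(
                scan_id=p.scan_id, sources=[src],
                destination=out_root / rel / src.name,
                action=action, scan_class=p.predicted_class,
                orientation=p.orientation or "", run=run,
            ))
    return SortPlan(root=out_root, entries=entries)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def execute_plan(plan: SortPlan, mode: str = "dry_run") -> pd.DataFrame:
    """Execute (or preview) a sort plan.

    ``dry_run`` touches nothing.  ``copy``/``move`` skip destinations whose
    content already matches (idempotent re-runs) and abort before any
    action if an existing destination differs from what would be written.
    Returns a report with one row per entry.
    """
    if mode not in ("dry_run", "copy", "move"):
        raise ValueError("mode must be dry_run, copy or move")

    if mode != "dry_run":
        # pre-flight: refuse to overwrite differing content anywhere
        for e in plan.entries:
            if e.action in ("copy", "move") and e.destination.exists():
                if _sha256(e.destination) != _sha256(e.sources[0]):
                    raise FileExistsError(
                        f"destination {e.destination} exists with different content; "
                        "aborting before any changes")

    rows = []
    for e in plan.entries:
        status = "planned"
        if mode != "dry_run":
            e.destination.parent.mkdir(parents=True, exist_ok=True)
            if e.action == "convert":
                if e.destination.exists():
                    status = "skipped"
                else:
                    vol = assemble_volume(
                        sorted(p for p in e.sources[0].rglob("*") if p.is_file()))
                    write_nifti(vol, e.destination)
                    status = "converted"
            else:
                src = e.sources[0]
                if e.destination.exists() and _sha256(e.destination) == _sha256(src):
                    status = "skipped"
                else:
                    if e.action == "move" or mode == "move":
                        shutil.move(str(src), str(e.destination))
                        status = "moved"
                    else:
                        shutil.copy2(str(src), str(e.destination))
                        status = "copied"
        rows.append({"scan_id": e.scan_id, "destination": str(e.destination),
                     "action": e.action, "status": status})
    if mode != "dry_run":
        for rel, content in plan.extra_files.items():
            path = plan.root / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(content)
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# metadata-heuristic baseline
# ---------------------------------------------------------------------------

@dataclass
class HeuristicRule:
    """One translation-table rule; the first matching rule (by ascending
    priority) decides the class."""

    priority: int
    output_class: str
    keywords_any: tuple[str, ...] = ()       # substrings of series/study description
    image_type_any: tuple[str, ...] = ()     # tokens of ImageType (case-insensitive)
    keywords_all: tuple[str, ...] = ()
    te_below_ms: Optional[float] = None
    te_at_least_ms: Optional[float] = None

    def matches(self, meta: SeriesMetadata) -> bool:
        desc = " ".join(filter(None, [meta.series_description or "",
                                      meta.study_description or ""])).lower()
        if self.image_type_any:
            tokens = {t.lower() for t in (meta.image_type or [])}
            if not tokens & {t.lower() for t in self.image_type_any}:
                return False
        if self.keywords_any and not any(k in desc for k in self.keywords_any):
            return False
        if any(k not in desc for k in self.keywords_all):
            return False
        if self.te_below_ms is not None:
            if meta.echo_time_ms is None or meta.echo_time_ms >= self.te_below_ms:
                return False
        if self.te_at_least_ms is not None:
            if meta.echo_time_ms is None or meta.echo_time_ms < self.te_at_least_ms:
                return False
        return True


#: shipped default rule table.  An honest, compact stand-in for the kind of
#: hand-tuned translation table practitioners write; descriptions are
#: matched case-insensitively, first hit wins.
DEFAULT_RULES: tuple[HeuristicRule, ...] = (
    HeuristicRule(10, "derived", image_type_any=("derived", "adc", "fa", "cbv", "cbf")),
    HeuristicRule(15, "derived", keywords_any=("adc", "rcbv", "fa map", "cbf")),
    HeuristicRule(20, "T2w-FLAIR", keywords_any=("flair", "dark fluid")),
    HeuristicRule(30, "T1wC", keywords_any=("t1",),
                  keywords_all=(),),  # refined below: contrast markers
    HeuristicRule(40, "T1w", keywords_any=("t1", "mprage", "spgr")),
    HeuristicRule(50, "DWI", keywords_any=("dwi", "diff", "trace")),
    HeuristicRule(60, "PWI-DSC", keywords_any=("perf", "dsc", "susc")),
    # dual-echo T2/PD: the echo time separates the two halves
    HeuristicRule(70, "PDw", keywords_any=("t2", "pd", "dual"), te_below_ms=30.0),
    HeuristicRule(80, "T2w", keywords_any=("t2",), te_at_least_ms=80.0),
    HeuristicRule(90, "T2w", keywords_any=("t2",)),
    HeuristicRule(95, "PDw", keywords_any=("pd", "proton")),
)
# contrast markers for the T1wC rule (kept separate so the rule table stays
# declarative): any of these alongside "t1" means post-contrast
_T1C_MARKERS = ("gd", "gad", "+c", "post", "contrast")


def heuristic_classify(meta: SeriesMetadata,
                       rules: Sequence[HeuristicRule] = DEFAULT_RULES) -> str:
    """First-matching-rule metadata classifier; returns 'unknown' if no rule fires."""
    desc = " ".join(filter(None, [meta.series_description or "",
                                  meta.study_description or ""])).lower()
    for rule in sorted(rules, key=lambda r: r.priority):
        if rule.output_class == "T1wC" and rule.keywords_any == ("t1",):
            if "t1" in desc and any(m in desc for m in _T1C_MARKERS):
                return "T1wC"
            continue
        if rule.matches(meta):
            return rule.output_class
    return "unknown"


def rules_to_json(rules: Sequence[HeuristicRule]) -> str:
    return json.dumps([r.__dict__ for r in rules], indent=2, default=list)


def rules_from_json(text: str) -> list[HeuristicRule]:
    out = []
    for d in json.loads(text):
        d = dict(d)
        for k in ("keywords_any", "image_type_any", "keywords_all"):
            d[k] = tuple(d.get(k, ()))
        out.append(HeuristicRule(**d))
    priorities = [r.priority for r in out]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    return out
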
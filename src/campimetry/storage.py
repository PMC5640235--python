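"""On-disk conventions: registries, identifiers, settings files, result folders.

* ``patients.s`` and ``screenLuminanceScales.s`` are append-only text
  databases, one tab-delimited record per line (tabs/newlines/backslashes
  in free text are backslash-escaped).  Writes go through a
  write-temp-then-swap so a crashed append never corrupts prior lines.
* Identifiers follow ``[PSR]_yyyyMMdd_xxxx`` where the prefix marks a
  patient, scale or result and ``xxxx`` is four random characters from
  lower/upper letters and digits.
* Settings templates (``*.sset``) are a documented ``key = value`` format
  grouped in sections; loading one reproduces the exam configuration
  exactly.  Compatibility with any other application's files is a
  non-goal.
* Every result folder ``Results/<P-id>/<R-id>/`` stores the presentation
  log, the dB map, a settings snapshot, the calibration measurements and a
  summary — enough to rebuild its map bit-for-bit (see
  :func:`rebuild_map`).
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import re
import string
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calibration import LuminanceScale, PhotometerMeasurement, fit_luminance_scale
from .engine import (
    BrightnessSpec,
    ExamConfig,
    ExamSession,
    KeyBindings,
    StimulusSpec,
)
from .errors import StorageError
from .fixation import FeedbackSpec, FixationConfig
from .geometry import FieldLocation, ScreenSetup
from .maps import VisualFieldMap, build_map
from .staircase import staircase_init, staircase_step

ID_PATTERN = re.compile(r"^[PSR]_\d{8}_[A-Za-z0-9]{4}$")
_ID_ALPHABET = string.ascii_lowercase + string.ascii_uppercase + string.digits


@dataclass(frozen=True)
class RecordId:
    prefix: str
    date: _dt.date
    suffix: str

    def __str__(self) -> str:
        return f"{self.prefix}_{self.date.strftime('%Y%m%d')}_{self.suffix}"

    @classmethod
    def parse(cls, text: str) -> "RecordId":
        if not ID_PATTERN.match(text):
            raise StorageError(f"malformed record id {text!r}")
        prefix, date, suffix = text.split("_")
        return cls(prefix, _dt.datetime.strptime(date, "%Y%m%d").date(), suffix)


def generate_id(prefix: str, date: _dt.date | None, rng, existing=()) -> str:
    """A fresh ``[PSR]_yyyyMMdd_xxxx`` identifier; regenerates on collision
    with ``existing``.  ``date`` defaults to today (inject a fixed date in
    tests)."""
    if prefix not in ("P", "S", "R"):
        raise StorageError(f"id prefix must be P, S or R, got {prefix!r}")
    if date is None:
        date = _dt.date.today()
    existing = set(existing)
    while True:
        suffix = "".join(rng.choice(_ID_ALPHABET) for _ in range(4))
        candidate = f"{prefix}_{date.strftime('%Y%m%d')}_{suffix}"
        if candidate not in existing:
            return candidate


# -- registries ----------------------------------------------------------


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


@dataclass(frozen=True)
class PatientRecord:
    id: str
    personal_info: str = ""
    additional_info: str = ""

    def to_fields(self) -> list[str]:
        return [self.id, self.personal_info, self.additional_info]

    @classmethod
    def from_fields(cls, fields: list[str]) -> "PatientRecord":
        if len(fields) != 3:
            raise StorageError(f"patient record needs 3 fields, got {len(fields)}")
        return cls(*fields)


@dataclass(frozen=True)
class ScaleRecord:
    id: str
    name: str
    hue: float
    saturation: float
    measurements: tuple[PhotometerMeasurement, ...]
    notes: str = ""

    def to_fields(self) -> list[str]:
        meas = ",".join(f"{m.brightness_pct}:{m.luminance!r}" for m in self.measurements)
        return [self.id, self.name, repr(self.hue), repr(self.saturation), meas, self.notes]

    @classmethod
    def from_fields(cls, fields: list[str]) -> "ScaleRecord":
        if len(fields) != 6:
            raise StorageError(f"scale record needs 6 fields, got {len(fields)}")
        try:
            measurements = tuple(
                PhotometerMeasurement(int(part.split(":")[0]), float(part.split(":")[1]))
                for part in fields[4].split(",")
            )
            return cls(fields[0], fields[1], float(fields[2]), float(fields[3]), measurements, fields[5])
        except (ValueError, IndexError) as exc:
            raise StorageError(f"unparseable scale record: {exc}") from exc

    def fit(self) -> LuminanceScale:
        return fit_luminance_scale(
            self.measurements, id=self.id, name=self.name, hue=self.hue,
            saturation=self.saturation, notes=self.notes,
        )

    @classmethod
    def from_scale(cls, scale: LuminanceScale) -> "ScaleRecord":
        return cls(scale.id, scale.name, scale.hue, scale.saturation, scale.measurements, scale.notes)


def read_registry(path, record_type):
    """All records of a ``.s`` registry file (empty or missing file → [])."""
    path = Path(path)
    if not path.exists():
        return []
    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = [_unescape(f) for f in line.split("\t")]
        try:
            records.append(record_type.from_fields(fields))
        except StorageError as exc:
            raise StorageError(f"{path}:{lineno}: {exc}") from exc
    return records


def append_record(path, record) -> None:
    """Append one record; writes to a temp file then atomically swaps so a
    crash cannot corrupt existing lines."""
    path = Path(path)
    line = "\t".join(_escape(f) for f in record.to_fields()) + "\n"
    existing = path.read_text() if path.exists() else ""
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(existing + line)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- settings templates (.sset) -----------------------------------------

_REQUIRED_SECTIONS = ("screen", "grid", "stimulus", "scales", "procedure", "fixation", "keys")


def _config_to_sections(config: ExamConfig) -> dict[str, dict[str, str]]:
    s, fx, fb = config.screen, config.fixation, config.fixation.feedback
    bs = fx.blindspot_location
    return {
        "screen": {
            "width_mm": repr(s.width_mm), "height_mm": repr(s.height_mm),
            "resolution_x": repr(s.resolution_x), "resolution_y": repr(s.resolution_y),
            "distance_mm": repr(s.distance_mm),
        },
        "grid": {
            "spacing_x_deg": repr(config.spacing_x_deg),
            "spacing_y_deg": repr(config.spacing_y_deg),
            "fixation_x_deg": repr(config.fixation_x_deg),
            "fixation_y_deg": repr(config.fixation_y_deg),
            "sphericity": str(config.sphericity).lower(),
        },
        "stimulus": {
            "shape": config.stimulus.shape,
            "width_deg": repr(config.stimulus.width_deg),
            "height_deg": repr(config.stimulus.height_deg),
            "inclination_deg": repr(config.stimulus.inclination_deg),
            "display_time_ms": repr(config.stimulus.display_time_ms),
            "isi_min_ms": repr(config.stimulus.isi_min_ms),
            "isi_max_ms": repr(config.stimulus.isi_max_ms),
        },
        "scales": {
            "stimulus_scale_id": config.stimulus_scale_id,
            "background_scale_id": config.background_scale_id,
            "background_brightness_pct": repr(config.background_brightness_pct),
        },
        "procedure": {
            "type": "basic",
            "min_brightness_pct": repr(config.brightness.min_pct),
            "max_brightness_pct": repr(config.brightness.max_pct),
            "vector_length": repr(config.brightness.length),
            "spread": config.brightness.spread,
            "seed": repr(config.seed),
        },
        "fixation": {
            "technique": fx.technique,
            "blindspot_location": (
                "default" if bs is None else f"{bs.x_deg!r},{bs.y_deg!r}"
            ),
            "control_brightness_pct": repr(fx.control_brightness_pct),
            "control_width_deg": repr(fx.control_width_deg),
            "control_height_deg": repr(fx.control_height_deg),
            "check_freq_min": repr(fx.check_freq_min),
            "check_freq_max": repr(fx.check_freq_max),
            "changed_point_size_deg": repr(fx.changed_point_size_deg),
            "changed_point_color": fx.changed_point_color,
            "feedback_enabled": str(fb.enabled).lower(),
            "feedback_text": fb.text,
            "feedback_position": fb.position,
            "feedback_color": fb.color,
            "feedback_font_size_pt": repr(fb.font_size_pt),
        },
        "keys": {
            "answer": config.keys.answer,
            "pause": config.keys.pause,
            "cancel": config.keys.cancel,
        },
    }


def save_settings(config: ExamConfig, path) -> None:
    """Write an exam configuration as a ``.sset`` settings template."""
    lines = []
    for section, entries in _config_to_sections(config).items():
        lines.append(f"[{section}]")
        lines.extend(f"{key} = {value}" for key, value in entries.items())
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _parse_sset(path) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
            continue
        if "=" not in line or current is None:
            raise StorageError(f"{path}:{lineno}: expected 'key = value' inside a section")
        key, _, value = line.partition("=")
        current[key.strip()] = value.strip()
    return sections


def load_settings(path) -> ExamConfig:
    """Load a ``.sset`` template back into an :class:`ExamConfig`.

    Missing required sections raise; unknown keys warn and are ignored.
    """
    sections = _parse_sset(path)
    missing = [s for s in _REQUIRED_SECTIONS if s not in sections]
    if missing:
        raise StorageError(f"{path}: missing required section(s): {', '.join(missing)}")
    known = _config_to_sections(_default_config())
    for section, entries in sections.items():
        unknown = set(entries) - set(known.get(section, {}))
        if section not in known or unknown:
            warnings.warn(
                f"{path}: ignoring unknown settings {sorted(unknown) or [section]}",
                stacklevel=2,
            )

    def get(section: str, key: str, conv=str):
        try:
            return conv(sections[section][key])
        except KeyError as exc:
            raise StorageError(f"{path}: missing key {section}.{key}") from exc

    as_bool = lambda v: v == "true"
    bs_text = get("fixation", "blindspot_location")
    blindspot = (
        None
        if bs_text == "default"
        else FieldLocation(*(float(v) for v in bs_text.split(",")))
    )
    return ExamConfig(
        screen=ScreenSetup(
            width_mm=get("screen", "width_mm", float),
            height_mm=get("screen", "height_mm", float),
            resolution_x=get("screen", "resolution_x", int),
            resolution_y=get("screen", "resolution_y", int),
            distance_mm=get("screen", "distance_mm", float),
        ),
        spacing_x_deg=get("grid", "spacing_x_deg", float),
        spacing_y_deg=get("grid", "spacing_y_deg", float),
        fixation_x_deg=get("grid", "fixation_x_deg", float),
        fixation_y_deg=get("grid", "fixation_y_deg", float),
        sphericity=get("grid", "sphericity", as_bool),
        stimulus=StimulusSpec(
            shape=get("stimulus", "shape"),
            width_deg=get("stimulus", "width_deg", float),
            height_deg=get("stimulus", "height_deg", float),
            inclination_deg=get("stimulus", "inclination_deg", float),
            display_time_ms=get("stimulus", "display_time_ms", float),
            isi_min_ms=get("stimulus", "isi_min_ms", float),
            isi_max_ms=get("stimulus", "isi_max_ms", float),
        ),
        brightness=BrightnessSpec(
            min_pct=get("procedure", "min_brightness_pct", float),
            max_pct=get("procedure", "max_brightness_pct", float),
            length=get("procedure", "vector_length", int),
            spread=get("procedure", "spread"),
        ),
        stimulus_scale_id=get("scales", "stimulus_scale_id"),
        background_scale_id=get("scales", "background_scale_id"),
        background_brightness_pct=get("scales", "background_brightness_pct", int),
        fixation=FixationConfig(
            technique=get("fixation", "technique"),
            blindspot_location=blindspot,
            control_brightness_pct=get("fixation", "control_brightness_pct", int),
            control_width_deg=get("fixation", "control_width_deg", float),
            control_height_deg=get("fixation", "control_height_deg", float),
            check_freq_min=get("fixation", "check_freq_min", int),
            check_freq_max=get("fixation", "check_freq_max", int),
            changed_point_size_deg=get("fixation", "changed_point_size_deg", float),
            changed_point_color=get("fixation", "changed_point_color"),
            feedback=FeedbackSpec(
                enabled=get("fixation", "feedback_enabled", as_bool),
                text=get("fixation", "feedback_text"),
                position=get("fixation", "feedback_position"),
                color=get("fixation", "feedback_color"),
                font_size_pt=get("fixation", "feedback_font_size_pt", int),
            ),
        ),
        keys=KeyBindings(
            answer=get("keys", "answer"),
            pause=get("keys", "pause"),
            cancel=get("keys", "cancel"),
        ),
        seed=get("procedure", "seed", int),
    )


def _default_config() -> ExamConfig:
    return ExamConfig(screen=ScreenSetup(535.0, 300.0, 1920, 1080, 370.0))


# -- result folders ------------------------------------------------------


def save_result(
    session: ExamSession,
    results_dir,
    patient_id: str,
    rng,
    date: _dt.date | None = None,
) -> Path:
    """Persist one finished session under ``Results/<P-id>/<R-id>/``.

    Writes ``session.csv`` (presentation log), ``map.csv`` (dB map),
    ``settings.sset``, ``scale.csv`` (photometer measurements of the
    stimulus scale) and ``summary.json``.  Returns the result folder path.
    """
    patient_dir = Path(results_dir) / patient_id
    patient_dir.mkdir(parents=True, exist_ok=True)
    existing = {p.name for p in patient_dir.iterdir() if p.is_dir()}
    result_id = generate_id("R", date, rng, existing)
    folder = patient_dir / result_id
    folder.mkdir()

    pd.DataFrame(
        [
            {
                "seq": r.seq,
                "time_ms": r.time_ms,
                "kind": r.kind,
                "loc_index": r.loc_index,
                "brightness_pct": r.brightness_pct,
                "luminance_cd_m2": r.luminance_cd_m2,
                "response": int(r.response),
                "verdict": r.verdict if r.verdict is not None else "",
            }
            for r in session.records
        ]
    ).to_csv(folder / "session.csv", index=False)

    vf_map = build_map(session)
    export_map_csv(vf_map, folder / "map.csv")
    save_settings(session.config, folder / "settings.sset")
    pd.DataFrame(
        [
            {"brightness_pct": m.brightness_pct, "luminance_cd_m2": m.luminance}
            for m in session.scale.measurements
        ]
    ).to_csv(folder / "scale.csv", index=False)

    summary = session.summary() | {
        "patient_id": patient_id,
        "result_id": result_id,
        "scale": {
            "id": session.scale.id,
            "name": session.scale.name,
            "hue": session.scale.hue,
            "saturation": session.scale.saturation,
        },
    }
    (folder / "summary.json").write_text(json.dumps(summary, indent=2))
    return folder


def export_map_csv(vf_map: VisualFieldMap, path) -> None:
    pd.DataFrame(
        {
            "x_deg": [loc.x_deg for loc in vf_map.locations],
            "y_deg": [loc.y_deg for loc in vf_map.locations],
            "db": vf_map.db_values,
        }
    ).to_csv(path, index=False)


def load_result_map(folder) -> VisualFieldMap:
    """The saved dB map of a result folder, with enough metadata restored
    (brightness vector, dB reference) for compatibility-checked
    subtraction and aggregation."""
    folder = Path(folder)
    config = load_settings(folder / "settings.sset")
    scale = _load_scale(folder)
    summary = json.loads((folder / "summary.json").read_text())
    df = pd.read_csv(folder / "map.csv")
    from .calibration import brightness_to_luminance

    l_max = brightness_to_luminance(scale, int(round(config.brightness.max_pct)))
    fx = config.fixation
    from .geometry import default_blindspot

    control = fx.blindspot_location
    if control is None:
        control = default_blindspot(summary.get("eye", "left"))
    return VisualFieldMap(
        locations=tuple(FieldLocation(x, y) for x, y in zip(df.x_deg, df.y_deg)),
        db_values=df.db.to_numpy(),
        l_max=l_max,
        eye=summary.get("eye", "left"),
        fixation=FieldLocation(config.fixation_x_deg, config.fixation_y_deg),
        control_location=control,
        metadata={"vector": config.brightness.make_vector().values, "summary": summary},
    )


def _load_scale(folder) -> LuminanceScale:
    folder = Path(folder)
    summary = json.loads((folder / "summary.json").read_text())
    meta = summary.get("scale", {})
    df = pd.read_csv(folder / "scale.csv")
    measurements = [
        PhotometerMeasurement(int(b), float(l))
        for b, l in zip(df.brightness_pct, df.luminance_cd_m2)
    ]
    return fit_luminance_scale(
        measurements,
        id=meta.get("id", ""),
        name=meta.get("name", ""),
        hue=meta.get("hue", 0.0),
        saturation=meta.get("saturation", 0.0),
    )


def rebuild_map(folder) -> VisualFieldMap:
    """Rebuild the dB map of a result folder from first principles.

    Replays the presentation log through fresh staircases, refits the
    luminance scale from the stored photometer measurements and rebuilds
    the map — it must agree bit-for-bit with the stored ``map.csv``.
    """
    folder = Path(folder)
    config = load_settings(folder / "settings.sset")
    scale = _load_scale(folder)
    summary = json.loads((folder / "summary.json").read_text())
    vector = config.brightness.make_vector()
    grid = config.make_grid()
    df = pd.read_csv(folder / "session.csv").sort_values("seq")

    states = {i: staircase_init(vector) for i in range(len(grid))}
    records = []
    for row in df.itertuples():
        if row.kind != "stimulus":
            continue
        idx = int(row.loc_index)
        states[idx] = staircase_step(states[idx], bool(row.response))

    from .engine import ResponseCounters
    from .geometry import default_blindspot

    eye = summary.get("eye", "left")
    control = config.fixation.blindspot_location
    if control is None:
        control = default_blindspot(eye)
    session = ExamSession(
        config=config,
        eye=eye,
        grid=grid,
        vector=vector,
        scale=scale,
        states=states,
        records=records,
        counters=ResponseCounters(),
        feedback_messages=[],
        duration_ms=summary.get("duration_ms", 0.0),
        control_location=control,
    )
    return build_map(session)
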
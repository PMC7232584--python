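"""Disease-severity parameter presets.

Six named presets span equilibration half-lives from 277 min (mildest) to
5 min (most severe), analogous to Hoehn & Yahr stages I-IV bracketed by
the mildest and most severely affected individuals.  The source
concentration-effect parameters per severity group are not reprinted
here, so the default EC50 and Hill-coefficient values are *illustrative*
placeholders (rising with severity); every field can be overridden from a
plain table or a JSON/YAML file of literature values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .pkpd_core import PDParams, ke_from_t_half, t_half_e

__all__ = [
    "SeverityPreset",
    "severity_presets",
    "presets_to_table",
    "presets_from_table",
    "load_presets",
    "save_presets",
    "DEFAULT_LABELS",
    "T_HALF_E_EXTREMES_MIN",
    "BASELINE_CBF",
    "MAX_EFFECT",
]

BASELINE_CBF = 50.0   # ml/hg/min
MAX_EFFECT = 35.0     # ml/hg/min above baseline

T_HALF_E_EXTREMES_MIN = (277.0, 5.0)  # mildest, most severe

DEFAULT_LABELS = ("mildest", "HY-I", "HY-II", "HY-III", "HY-IV", "most-severe")

# illustrative placeholder ranges, increasing with severity (override-first)
_EC50_RANGE_NG_ML = (400.0, 1500.0)
_HILL_RANGE = (2.0, 8.0)


@dataclass(frozen=True)
class SeverityPreset:
    """A named pharmacodynamic parameter set for one severity level."""

    label: str
    params: PDParams

    @property
    def t_half_e(self) -> float:
        return t_half_e(self.params.ke)


def _default_rows() -> list[dict]:
    n_presets = len(DEFAULT_LABELS)
    t_half = np.geomspace(*T_HALF_E_EXTREMES_MIN, n_presets)
    ec50 = np.geomspace(*_EC50_RANGE_NG_ML, n_presets)
    hill = np.linspace(*_HILL_RANGE, n_presets)
    return [
        {
            "label": lab,
            "t_half_e_min": float(th),
            "ec50": float(c),
            "n": float(h),
            "e0": BASELINE_CBF,
            "emax": MAX_EFFECT,
        }
        for lab, th, c, h in zip(DEFAULT_LABELS, t_half, ec50, hill)
    ]


def presets_from_table(rows: list[dict]) -> list[SeverityPreset]:
    """Build presets from a list of row dicts.

    Each row needs ``label`` plus either ``t_half_e_min`` or ``ke``, and
    ``ec50``, ``n``; ``e0``/``emax`` default to the standard baseline and
    maximal effect.  Rows must be ordered from mildest to most severe
    (strictly increasing ke).
    """
    presets = []
    for row in rows:
        if "ke" in row:
            ke = float(row["ke"])
        elif "t_half_e_min" in row:
            ke = ke_from_t_half(float(row["t_half_e_min"]))
        else:
            raise ParameterError(f"row {row.get('label')!r} needs 't_half_e_min' or 'ke'")
        params = PDParams(
            e0=float(row.get("e0", BASELINE_CBF)),
            emax=float(row.get("emax", MAX_EFFECT)),
            ec50=float(row["ec50"]),
            n=float(row["n"]),
            ke=ke,
        )
        presets.append(SeverityPreset(label=str(row["label"]), params=params))
    kes = [p.params.ke for p in presets]
    if not all(a < b for a, b in zip(kes, kes[1:])):
        raise ParameterError("presets must be strictly ordered by increasing ke")
    return presets


def presets_to_table(presets: list[SeverityPreset]) -> list[dict]:
    return [
        {
            "label": p.label,
            "t_half_e_min": float(p.t_half_e),
            "ec50": float(p.params.ec50),
            "n": float(p.params.n),
            "e0": float(p.params.e0),
            "emax": float(p.params.emax),
        }
        for p in presets
    ]


def severity_presets(overrides: list[dict] | None = None) -> list[SeverityPreset]:
    """Ordered severity presets, mildest first.

    With no overrides, returns six defaults whose equilibration half-lives
    are log-spaced with extremes exactly 277 and 5 min, all with
    e0 = 50 and emax = 35 ml/hg/min.  ``overrides`` replaces the whole
    table (same row format as :func:`presets_from_table`).
    """
    rows = overrides if overrides is not None else _default_rows()
    return presets_from_table(rows)


def save_presets(presets: list[SeverityPreset], path: str | Path) -> None:
    """Serialize presets to JSON or YAML (by file extension)."""
    path = Path(path)
    table = presets_to_table(presets)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(table, sort_keys=False))
    else:
        path.write_text(json.dumps(table, indent=2))


def load_presets(path: str | Path) -> list[SeverityPreset]:
    """Load presets from a JSON or YAML table written by :func:`save_presets`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        rows = yaml.safe_load(text)
    else:
        rows = json.loads(text)
    return presets_from_table(rows)
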
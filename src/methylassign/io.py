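"""File formats, run configuration and logging shared by all modules.

Tabular interchange is TSV throughout (peaks, shift predictions, PRE
observations/predictions, NOE peaks, contact graphs), read and written with
pandas. Peak lists additionally accept a Sparky-like whitespace dialect
(``assignment w1 w2 height`` columns, w1 = 13C, w2 = 1H).

Final assignments can be exported as (and re-imported from) an NMR-STAR 3.1
chemical-shift saveframe subset — one ``_Atom_chem_shift`` loop row per
assigned nucleus, with ambiguity code 1 for stereo-resolved methyls and 2
for geminal pairs left stereo-ambiguous. The writer/parser covers only that
subset, is lossless on its own output, and accepts both HD1/HD2 and
QD1/QD2 proton naming conventions on input.

All ppm axes are stored as (dH, dC) pairs; nothing is ever stored in Hz.
Methyl identifiers follow the grammar ``<one-letter><residue number>-<pseudo>``
(e.g. ``L315-QD1``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .engine import AssignmentState, Peak, PeakList
from .noe import NOEPeak
from .pre import PREObservation, PREPrediction
from .shifts import MergedPrediction, ShiftPredictionRecord
from .structure import MethylGroup

logger = logging.getLogger("methylassign")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ------------------------------------------------------------------ config

@dataclass
class RunConfig:
    """Flat run configuration mirroring the module parameters.

    Loaded from YAML; every CLI flag overrides the corresponding entry.
    Evidence weights are normalized to sum to 1 on load.
    """

    tol_h: float = 0.02          # ppm
    tol_c: float = 0.2           # ppm
    noe_cutoff: float = 8.0      # A
    weight_noe: float = 0.5
    weight_shift: float = 0.3
    weight_pre: float = 0.2
    threshold: float = 0.4
    margin: float = 0.1
    h1_freq_hz: float = 850e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_h <= 0 or self.tol_c <= 0:
            raise ValueError("tolerances must be positive")
        total = self.weight_noe + self.weight_shift + self.weight_pre
        if total <= 0:
            raise ValueError("evidence weights must have positive sum")
        self.weight_noe /= total
        self.weight_shift /= total
        self.weight_pre /= total

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ------------------------------------------------------------------ peak lists

def read_peaklist(path: str | Path, dialect: str = "tsv",
                  spectrum_id: Optional[str] = None,
                  scheme: str = "IMLV[rac]") -> PeakList:
    """Read a 2D methyl peak list.

    ``tsv`` expects columns id, dH_ppm, dC_ppm and optionally intensity and
    form. ``sparky`` expects whitespace-separated ``assignment w1 w2 height``
    with w1 = 13C ppm and w2 = 1H ppm. Malformed rows raise with their line
    number.
    """
    path = Path(path)
    sid = spectrum_id or path.stem
    peaks: list[Peak] = []
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"id", "dH_ppm", "dC_ppm"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: need columns {sorted(required)}")
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            try:
                peaks.append(Peak(
                    id=row.id,
                    dh=float(row.dH_ppm),
                    dc=float(row.dC_ppm),
                    intensity=float(getattr(row, "intensity", "") or 1.0),
                    form=getattr(row, "form", "") or "unknown"))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{row_no}: malformed row ({exc})")
    elif dialect == "sparky":
        with open(path) as fh:
            for row_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.lower().startswith("assignment"):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{row_no}: expected at least "
                                     "'assignment w1 w2'")
                try:
                    w1, w2 = float(parts[1]), float(parts[2])
                    height = float(parts[3]) if len(parts) > 3 else 1.0
                except ValueError as exc:
                    raise ValueError(f"{path}:{row_no}: malformed row ({exc})")
                peaks.append(Peak(parts[0], dh=w2, dc=w1, intensity=height))
    else:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    return PeakList(sid, scheme, peaks)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    df = pd.DataFrame(
        [{"id": p.id, "dH_ppm": p.dh, "dC_ppm": p.dc,
          "intensity": p.intensity, "form": p.form} for p in peaklist.peaks],
        columns=["id", "dH_ppm", "dC_ppm", "intensity", "form"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ------------------------------------------------------------------ predictions

def read_predictions(path: str | Path) -> list[ShiftPredictionRecord]:
    """Prediction TSV: methyl_id, nucleus, value_ppm, uncertainty_ppm, source."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            unc = row.uncertainty_ppm.strip() if hasattr(row, "uncertainty_ppm") else ""
            out.append(ShiftPredictionRecord(
                methyl_id=row.methyl_id, nucleus=row.nucleus,
                value=float(row.value_ppm),
                uncertainty=float(unc) if unc else None,
                source=getattr(row, "source", "A") or "A"))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{row_no}: malformed row ({exc})")
    return out


def write_merged(merged: Sequence[MergedPrediction], path: str | Path) -> None:
    pd.DataFrame(
        [{"methyl_id": m.methyl_id, "nucleus": m.nucleus, "value_ppm": m.value,
          "uncertainty_ppm": m.uncertainty, "provenance": m.provenance}
         for m in merged]).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_merged(path: str | Path) -> list[MergedPrediction]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [MergedPrediction(r.methyl_id, r.nucleus, float(r.value_ppm),
                             float(r.uncertainty_ppm), r.provenance)
            for r in df.itertuples(index=False)]


# ------------------------------------------------------------------ PRE tables

def read_pre_observations(path: str | Path) -> list[PREObservation]:
    """PRE observation TSV: key, I_para, I_dia, quantifiable."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        out.append(PREObservation(
            key=r.key, i_para=float(r.I_para), i_dia=float(r.I_dia),
            quantifiable=bool(r.quantifiable)))
    return out


def write_pre_observations(obs: Sequence[PREObservation],
                           path: str | Path) -> None:
    pd.DataFrame(
        [{"key": o.key, "I_para": o.i_para, "I_dia": o.i_dia,
          "quantifiable": o.quantifiable} for o in obs]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_pre_predictions(preds: Sequence[PREPrediction],
                          path: str | Path) -> None:
    pd.DataFrame(
        [{"methyl_id": p.methyl_id, "r_eN_A": p.r_en, "Gamma2_H": p.gamma2_h,
          "Gamma2_MQ": p.gamma2_mq, "ratio": p.ratio} for p in preds]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ------------------------------------------------------------------ NOE tables

def read_noe_peaks(path: str | Path, layout: str = "hcch") -> list[NOEPeak]:
    """NOE peak TSV with a declared layout: hch | cch | hcch.

    Columns are the present dimensions in order (H1_ppm, C1_ppm, C2_ppm,
    H2_ppm as applicable) plus optional intensity, spectrum_id, mixing_time.
    """
    layouts = {"hch": ("H1_ppm", "C1_ppm", None, "H2_ppm"),
               "cch": (None, "C1_ppm", "C2_ppm", "H2_ppm"),
               "hcch": ("H1_ppm", "C1_ppm", "C2_ppm", "H2_ppm")}
    if layout not in layouts:
        raise ValueError(f"unknown NOE layout {layout!r}")
    cols = layouts[layout]
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        dims = [float(getattr(r, c)) if c else None for c in cols]
        out.append(NOEPeak(
            h1=dims[0], c1=dims[1], c2=dims[2], h2=dims[3],
            intensity=float(getattr(r, "intensity", 1.0)),
            spectrum_id=str(getattr(r, "spectrum_id", "")),
            mixing_time=float(r.mixing_time) if hasattr(r, "mixing_time") else None))
    return out


def write_noe_peaks(peaks: Sequence[NOEPeak], path: str | Path) -> None:
    pd.DataFrame(
        [{"H1_ppm": p.h1, "C1_ppm": p.c1, "C2_ppm": p.c2, "H2_ppm": p.h2,
          "intensity": p.intensity, "spectrum_id": p.spectrum_id,
          "mixing_time": p.mixing_time} for p in peaks]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ------------------------------------------------------------------ NMR-STAR

#: methyl pseudo-atom -> (carbon atom, proton atom) deposition names
_STAR_ATOMS = {"QD1": ("CD1", "HD1"), "QD2": ("CD2", "HD2"),
               "QG1": ("CG1", "HG1"), "QG2": ("CG2", "HG2"),
               "QE": ("CE", "HE")}
_STAR_ATOMS_REV = {c: q for q, (c, _h) in _STAR_ATOMS.items()}
_STAR_ATOMS_REV.update({h: q for q, (_c, h) in _STAR_ATOMS.items()})
#: alternative proton naming (QD1 etc. used directly) also accepted on read
_ONE_TO_THREE = {"I": "ILE", "L": "LEU", "V": "VAL", "M": "MET"}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}

_ID_RE = re.compile(r"^([ILVM])(\d+)-(Q[DGE]\d?)$")


def parse_methyl_id(methyl_id: str) -> tuple[str, int, str]:
    """Split ``L315-QD1`` into (residue type three-letter, number, pseudo)."""
    m = _ID_RE.match(methyl_id)
    if not m:
        raise ValueError(f"malformed methyl id {methyl_id!r}")
    return _ONE_TO_THREE[m.group(1)], int(m.group(2)), m.group(3)


def write_nmrstar(state: AssignmentState, methyls: Sequence[MethylGroup],
                  peaks_by_id: dict[str, Peak], entry_id: str = "assignment",
                  ) -> str:
    """Render the assignment as an NMR-STAR 3.1 chemical-shift saveframe.

    One loop row per assigned nucleus (C then H per methyl), ordered by
    (residue number, pseudo-atom). Ambiguity code 2 marks members of
    stereo-ambiguous geminal pairs, 1 everything else.
    """
    ambiguous_ids = {m for pair in state.stereo_ambiguous for m in pair}
    rows = []
    for m in sorted(methyls, key=MethylGroup.sort_key):
        pid = state.assignments.get(m.id)
        if pid is None or pid not in peaks_by_id:
            continue
        peak = peaks_by_id[pid]
        carbon, proton = _STAR_ATOMS[m.pseudo_name]
        code = 2 if m.id in ambiguous_ids else 1
        rows.append((m.residue_number, m.residue_type, carbon, "C", peak.dc, code))
        rows.append((m.residue_number, m.residue_type, proton, "H", peak.dh, code))
    lines = [f"data_{entry_id}", "",
             "save_assigned_chemical_shifts",
             "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
             "   _Assigned_chem_shift_list.ID            1",
             "",
             "   loop_",
             "      _Atom_chem_shift.ID",
             "      _Atom_chem_shift.Comp_index_ID",
             "      _Atom_chem_shift.Comp_ID",
             "      _Atom_chem_shift.Atom_ID",
             "      _Atom_chem_shift.Atom_type",
             "      _Atom_chem_shift.Val",
             "      _Atom_chem_shift.Ambiguity_code",
             ""]
    for i, (num, rtype, atom, atype, val, code) in enumerate(rows, start=1):
        lines.append(f"      {i:4d} {num:4d} {rtype} {atom:4s} {atype} "
                     f"{val:8.3f} {code}")
    lines += ["   stop_", "", "save_", ""]
    return "\n".join(lines)


@dataclass(frozen=True)
class StarShiftRow:
    residue_number: int
    residue_type: str
    atom: str
    atom_type: str
    value: float
    ambiguity: int

    @property
    def methyl_id(self) -> Optional[str]:
        pseudo = (self.atom if self.atom.startswith("Q")
                  else _STAR_ATOMS_REV.get(self.atom))
        one = _THREE_TO_ONE.get(self.residue_type)
        if pseudo is None or one is None:
            return None
        return f"{one}{self.residue_number}-{pseudo}"


def read_nmrstar(text_or_path: str | Path) -> list[StarShiftRow]:
    """Parse the chemical-shift loop subset written by :func:`write_nmrstar`.

    Accepts a path or a document string; rows with unknown atoms are kept
    (their ``methyl_id`` is None) and logged. Raises when no parseable
    ``_Atom_chem_shift`` loop is found.
    """
    p = Path(str(text_or_path))
    if "\n" not in str(text_or_path) and p.exists():
        text = p.read_text()
    else:
        text = str(text_or_path)
    lines = text.splitlines()
    rows: list[StarShiftRow] = []
    tags: list[str] = []
    in_loop = in_body = False
    found_loop = False
    for line in lines:
        s = line.strip()
        if s == "loop_":
            in_loop, in_body, tags = True, False, []
            continue
        if not in_loop:
            continue
        if s.startswith("_"):
            tags.append(s.split(".")[-1])
            continue
        if s == "stop_":
            if not {"Comp_index_ID", "Atom_ID", "Val"} - set(tags):
                found_loop = True
            in_loop = in_body = False
            continue
        if not s:
            continue
        # first non-tag line: loop body
        if {"Comp_index_ID", "Atom_ID", "Val"} - set(tags):
            in_loop = False  # some other loop; skip
            continue
        found_loop = True
        vals = s.split()
        if len(vals) != len(tags):
            raise ValueError(f"malformed loop row: {s!r}")
        rec = dict(zip(tags, vals))
        row = StarShiftRow(
            residue_number=int(rec["Comp_index_ID"]),
            residue_type=rec.get("Comp_ID", "").upper(),
            atom=rec["Atom_ID"],
            atom_type=rec.get("Atom_type", "?"),
            value=float(rec["Val"]),
            ambiguity=int(rec.get("Ambiguity_code", 1)))
        if row.methyl_id is None:
            logger.warning("skipping unknown atom %s %s%d", row.atom,
                           row.residue_type, row.residue_number)
        rows.append(row)
    if not found_loop:
        raise ValueError("no _Atom_chem_shift loop found")
    return rows


def assignment_table(state: AssignmentState, peaks_by_id: dict[str, Peak],
                     ) -> pd.DataFrame:
    """Assignment TSV content: methyl_id, peak_id, dH, dC, confidence, evidence."""
    rows = []
    for mid, pid in sorted(state.assignments.items()):
        peak = peaks_by_id.get(pid)
        rows.append({"methyl_id": mid, "peak_id": pid,
                     "dH_ppm": peak.dh if peak else float("nan"),
                     "dC_ppm": peak.dc if peak else float("nan"),
                     "confidence": state.confidence.get(mid, float("nan")),
                     "evidence": "+".join(state.evidence.get(mid, []))})
    return pd.DataFrame(rows, columns=["methyl_id", "peak_id", "dH_ppm",
                                       "dC_ppm", "confidence", "evidence"])
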
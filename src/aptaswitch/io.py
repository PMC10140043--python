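"""Readers and writers for the package's file formats.

FASTA for sequences (with ``key=value`` annotations in the description,
e.g. ``cds_start=75``), YAML for aptamer specs and calibration, long-form
CSV for plate-reader data plus a well-map CSV, TSV for tabular results,
and JSON for full-precision prediction round trips.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay import KineticTrace, TraceRole
from .energy import MrnaRecord
from .switch import AptamerSpec, Mode, RiboswitchConstruct, SwitchPrediction


# -- FASTA ----------------------------------------------------------------


def _header_fields(description: str) -> dict[str, str]:
    return dict(
        tok.split("=", 1) for tok in description.split() if "=" in tok
    )


def read_mrna_fasta(path: str | Path, cds_start: int | None = None) -> list[MrnaRecord]:
    """Read mRNA records; cds_start from the header (cds_start=N) or arg."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = _header_fields(rec.description)
        start = int(fields.get("cds_start", cds_start or 0))
        if start <= 0:
            raise ValueError(
                f"{rec.id}: no cds_start in header and none supplied"
            )
        out.append(MrnaRecord(rec.id, str(rec.seq), start))
    return out


def write_mrna_fasta(records: list[MrnaRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(m.sequence), id=m.name, description=f"cds_start={m.cds_start}")
        for m in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_construct_fasta(
    constructs: list[RiboswitchConstruct], path: str | Path
) -> None:
    """Assembled constructs with region offsets annotated in the header."""
    seqs = []
    for c in constructs:
        lo, hi = c.aptamer_span
        desc = (
            f"pre=1-{len(c.pre_aptamer)} aptamer={lo}-{hi} "
            f"post={hi + 1}-{c.cds_start - 1} cds_start={c.cds_start} "
            f"mode={c.mode.value} aptamer_name={c.aptamer.name}"
        )
        seqs.append(SeqRecord(Seq(c.sequence), id=c.name, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


# -- construct TSV --------------------------------------------------------

_CONSTRUCT_COLS = ["name", "pre_aptamer", "post_aptamer", "cds", "mode"]


def write_constructs_tsv(constructs: list[RiboswitchConstruct], path: str | Path) -> None:
    rows = [
        {
            "name": c.name,
            "pre_aptamer": c.pre_aptamer,
            "post_aptamer": c.post_aptamer,
            "cds": c.cds,
            "mode": c.mode.value,
        }
        for c in constructs
    ]
    pd.DataFrame(rows, columns=_CONSTRUCT_COLS).to_csv(path, sep="\t", index=False)


def read_constructs_tsv(
    path: str | Path, aptamer: AptamerSpec
) -> list[RiboswitchConstruct]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        RiboswitchConstruct(
            name=row["name"],
            pre_aptamer=row["pre_aptamer"],
            aptamer=aptamer,
            post_aptamer=row["post_aptamer"],
            cds=row["cds"],
            mode=Mode(row["mode"]),
        )
        for row in df.to_dict("records")
    ]


# -- aptamer YAML ----------------------------------------------------------


def write_aptamer_yaml(aptamer: AptamerSpec, path: str | Path) -> None:
    data = {
        "name": aptamer.name,
        "sequence": aptamer.sequence,
        "bound_structure": aptamer.bound_structure,
        "kd_nM": aptamer.kd * 1e9,
        "ligand": aptamer.ligand_name,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_aptamer_yaml(path: str | Path) -> AptamerSpec:
    d = yaml.safe_load(Path(path).read_text())
    return AptamerSpec(
        name=d["name"],
        sequence=d["sequence"],
        bound_structure=d["bound_structure"],
        kd=float(d["kd_nM"]) * 1e-9,
        ligand_name=d.get("ligand", ""),
    )


# -- plate CSV + well map --------------------------------------------------


def write_plate_csv(
    traces: list[KineticTrace], plate_path: str | Path, map_path: str | Path
) -> None:
    """Long-format plate CSV (time_min, well, fluorescence) + well map."""
    rows = []
    for t in traces:
        for tm, fl in zip(t.times, t.fluorescence):
            rows.append({"time_min": tm, "well": t.well, "fluorescence": fl})
    pd.DataFrame(rows).to_csv(plate_path, index=False, float_format="%.17g")
    wm = [
        {
            "well": t.well,
            "construct": t.construct,
            "role": t.role.value,
            "ligand_conc_nM": t.ligand_conc * 1e9,
            "replicate": t.replicate,
        }
        for t in traces
    ]
    pd.DataFrame(wm).to_csv(map_path, index=False, float_format="%.17g")


def read_plate_csv(plate_path: str | Path, map_path: str | Path) -> list[KineticTrace]:
    plate = pd.read_csv(plate_path, float_precision="round_trip")
    wmap = pd.read_csv(map_path, float_precision="round_trip").set_index("well")
    traces = []
    for well, grp in plate.groupby("well", sort=False):
        grp = grp.sort_values("time_min")
        meta = wmap.loc[well]
        traces.append(
            KineticTrace(
                well=str(well),
                times=tuple(grp["time_min"].to_numpy(dtype=float)),
                fluorescence=tuple(grp["fluorescence"].to_numpy(dtype=float)),
                construct=str(meta["construct"]),
                ligand_conc=float(meta["ligand_conc_nM"]) * 1e-9,
                replicate=int(meta["replicate"]),
                role=TraceRole(meta["role"]),
            )
        )
    return traces


# -- results ----------------------------------------------------------------


def write_predictions_tsv(preds: list[SwitchPrediction], path: str | Path) -> None:
    pd.DataFrame([p.to_dict() for p in preds]).to_csv(path, sep="\t", index=False)


def prediction_to_json(pred: SwitchPrediction) -> str:
    """Full-precision JSON of the scalar prediction fields."""
    return json.dumps(pred.to_dict())


def prediction_ratios_from_json(payload: str) -> dict:
    return json.loads(payload)
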
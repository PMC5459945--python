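"""Tabular report writers: every TSV gets a machine-readable JSON twin."""

from __future__ import annotations

import json
from pathlib import Path

SCORE_COLUMNS = ["score", "total_precursor_supporting_reactions", "avg_precursor_reactions_per_efm"]
DESIGN_COLUMNS = [
    "cutset",
    "valve",
    "restored_growth_fraction",
    "score",
    "precursors_off",
    "product_yield_off",
]
ENVELOPE_COLUMNS = ["fraction", "biomass", "product_min", "product_max"]


def fmt(x) -> str:
    """Floats at 4 significant digits; everything else verbatim."""
    if isinstance(x, bool) or x is None:
        return str(x)
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def write_tsv(path: str | Path, columns: list[str], rows: list[dict]) -> None:
    path = Path(path)
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(fmt(row.get(c)) for c in columns))
    path.write_text("\n".join(lines) + "\n")


def write_report(path: str | Path, columns: list[str], rows: list[dict], meta: dict | None = None) -> None:
    """Write a TSV table plus its JSON twin next to it."""
    path = Path(path)
    write_tsv(path, columns, rows)
    payload = {"columns": columns, "rows": rows}
    if meta:
        payload["meta"] = meta
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n"
    )


def score_rows(result, name: str) -> list[dict]:
    return [
        {
            "name": name,
            "score": result.score,
            "total_precursor_supporting_reactions": result.total_precursor_reactions,
            "avg_precursor_reactions_per_efm": result.avg_precursor_reactions_per_efm,
        }
    ]


def design_rows(designs) -> list[dict]:
    return [
        {
            "cutset": ",".join(sorted(d.cutset.reaction_ids)),
            "valve": d.valve_id,
            "restored_growth_fraction": d.restored_growth_fraction,
            "score": d.score_valve_on if not d.score_undefined else "undefined",
            "precursors_off": d.precursors_off_count,
            "product_yield_off": d.product_yield_valve_off,
        }
        for d in designs
    ]


def envelope_rows(envelopes) -> list[dict]:
    rows = []
    for env in envelopes:
        for biomass, pmin, pmax in env.points:
            rows.append(
                {
                    "fraction": env.valve_fraction,
                    "biomass": biomass,
                    "product_min": pmin,
                    "product_max": pmax,
                }
            )
    return rows
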
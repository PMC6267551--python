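"""File input/output: counts CSV, hypothesis configs, BF tables, reports.

Counts are exchanged in wide CSV format — header ``person_id,<cond1>,...``,
one row per person, with the replication count supplied by the hypothesis
config (constant across conditions and persons).  Hypothesis configs are
YAML or JSON mapping labels to constraint strings (or explicit matrices).
Per-person Bayes factors can be ingested from long CSV with optional
censoring flags for published values recorded as bounds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .aggregate import AggregateSummary, BFVector
from .bayes import PersonEvaluation
from .hypotheses import (
    ConditionLayout,
    ConstraintMatrix,
    Hypothesis,
    HypothesisSet,
    parse_hypothesis,
)
from .model import PersonCounts

__all__ = [
    "read_counts",
    "read_hypothesis_config",
    "read_bf_table",
    "write_counts",
    "evaluations_to_frame",
    "summaries_to_frame",
    "write_report",
    "generate_fixture",
    "FIXTURE_NAMES",
]


def read_hypothesis_config(path) -> HypothesisSet:
    """Load a hypothesis config (YAML or JSON).

    Expected keys: ``conditions`` (list of names), ``replications`` (R), and
    ``hypotheses`` (map label -> constraint string, or label -> list of
    coefficient rows for an explicit matrix).
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    for key in ("conditions", "replications", "hypotheses"):
        if key not in cfg:
            raise ValueError(f"hypothesis config is missing the {key!r} key")
    layout = ConditionLayout(cfg["conditions"], cfg["replications"])
    hyps = []
    for label, spec in cfg["hypotheses"].items():
        if isinstance(spec, str):
            hyps.append(parse_hypothesis(spec, layout, label=str(label)))
        else:
            hyps.append(
                Hypothesis(str(label), "informative", ConstraintMatrix(np.asarray(spec)))
            )
    return HypothesisSet(hyps, layout)


def read_counts(path, layout: ConditionLayout) -> list[PersonCounts]:
    """Read wide-format counts CSV and validate against the layout."""
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise ValueError("counts file must have a 'person_id' column")
    missing = [n for n in layout.names if n not in df.columns]
    if missing:
        raise ValueError(f"counts file is missing condition columns: {missing}")
    if len(df) == 0:
        raise ValueError("counts file contains no persons")
    ids = df["person_id"].astype(str)
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate person ids: {sorted(set(dupes))}")
    persons = []
    for _, row in df.iterrows():
        pid = str(row["person_id"])
        values = []
        for name in layout.names:
            cell = row[name]
            if pd.isna(cell) or float(cell) != int(cell):
                raise ValueError(
                    f"non-integer count for person {pid!r}, condition {name!r}: {cell!r}"
                )
            v = int(cell)
            if not 0 <= v <= layout.replications:
                raise ValueError(
                    f"count out of range [0, {layout.replications}] for person "
                    f"{pid!r}, condition {name!r}: {v}"
                )
            values.append(v)
        persons.append(PersonCounts(pid, values, layout))
    return persons


def write_counts(persons: list[PersonCounts], path) -> None:
    layout = persons[0].layout
    rows = [
        {"person_id": p.person_id, **dict(zip(layout.names, p.successes.tolist()))}
        for p in persons
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bf_table(path) -> dict[str, BFVector]:
    """Read a long CSV of per-person Bayes factors into vectors per comparison.

    Columns: ``person``, ``comparison``, ``bf``, optional ``censor``
    (empty, ``lt`` or ``gt``).
    """
    df = pd.read_csv(path)
    for col in ("person", "comparison", "bf"):
        if col not in df.columns:
            raise ValueError(f"BF table is missing the {col!r} column")
    out = {}
    for comp, grp in df.groupby("comparison", sort=False):
        censored = None
        if "censor" in grp.columns:
            censored = [
                None if (pd.isna(c) or c == "") else str(c) for c in grp["censor"]
            ]
        out[str(comp)] = BFVector(
            grp["bf"].to_numpy(float), comparison=str(comp), censored=censored
        )
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def evaluations_to_frame(evaluations: list[PersonEvaluation]) -> pd.DataFrame:
    """Machine-readable per-person table (full precision)."""
    rows = []
    for ev in evaluations:
        for m in ev.labels:
            rows.append(
                {
                    "person": ev.person_id,
                    "hypothesis": m,
                    "complexity": ev.complexity[m].best,
                    "se_complexity": ev.complexity[m].std_error,
                    "fit": ev.fit[m].value,
                    "se_fit": ev.fit[m].std_error,
                    "bf_vs_unconstrained": float(ev.bf_u[m]),
                    "bf_vs_complement": float(ev.bf_c[m]),
                    "best": (ev.decision.best if ev.decision else None),
                    "threshold": (ev.decision.threshold if ev.decision else None),
                }
            )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[AggregateSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": s.comparison,
                "P": s.n_persons,
                "p_bf": s.p_bf,
                "gp_bf": s.gp_bf,
                "er": s.er,
                "sr": s.sr,
                "flags": ";".join(s.flags),
            }
            for s in summaries
        ]
    )


def write_report(frame: pd.DataFrame, path, rounding: int = 2) -> None:
    """Write a machine CSV plus a human-readable 2-decimal text summary.

    ``path`` is the CSV target; the summary goes to ``<path>.txt``.  An
    empty frame yields header-only files.
    """
    path = Path(path)
    frame.to_csv(path, index=False)
    txt = path.with_suffix(path.suffix + ".txt")
    if len(frame) == 0:
        txt.write_text("(no results)\n")
        return
    shown = frame.copy()
    for col in shown.columns:
        if pd.api.types.is_float_dtype(shown[col]):
            shown[col] = shown[col].round(rounding)
    txt.write_text(shown.to_string(index=False) + "\n")


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table1", "table2", "table3")


def generate_fixture(name: str, outdir) -> list[Path]:
    """Write a named worked-example dataset to disk; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "table1":
        counts_path = outdir / "table1_counts.csv"
        write_counts(datasets.table1_persons(), counts_path)
        cfg = {
            "conditions": list(datasets.table1_layout().names),
            "replications": datasets.table1_layout().replications,
            "hypotheses": {
                "H1": "c1 > c2 > c3 > c4",
                "H2": "(c1 + c2)/2 > (c3 + c4)/2",
            },
        }
        cfg_path = outdir / "table1_hypotheses.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        return [counts_path, cfg_path]
    if name == "table3":
        rows = []
        for set_id, values in datasets.TABLE3_SETS.items():
            for i, bf in enumerate(values, start=1):
                rows.append(
                    {"person": i, "comparison": f"set{set_id}", "bf": bf, "censor": ""}
                )
        path = outdir / "table3_bf.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path]
    if name == "table2":
        rows = []
        for column, values in datasets.TABLE2_COLUMNS.items():
            flags = datasets.table2_censor_flags(column)
            for i, (bf, cens) in enumerate(zip(values, flags), start=1):
                rows.append(
                    {
                        "person": i,
                        "comparison": column,
                        "bf": bf,
                        "censor": cens if cens else "",
                    }
                )
        path = outdir / "table2_bf.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path]
    raise ValueError(f"unknown fixture name: {name!r}; choose from {FIXTURE_NAMES}")
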
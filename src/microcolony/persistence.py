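"""Relational results store and run artifacts.

The analysis of a movie condenses into five tables — Experiment, Frame,
Colony, CellInstant (time-varying attributes) and Cell (whole-life
attributes) — written both as a SQLite database with enforced referential
integrity and as greppable CSV mirrors.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = ["ExperimentRecord", "export_database", "foreign_key_audit"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS experiment (
    experiment_id INTEGER PRIMARY KEY,
    description TEXT, modality TEXT, species TEXT,
    cell_length_um REAL, cell_width_um REAL,
    cal_factor REAL, sampling_period_min REAL,
    pipeline_version TEXT, rng_seed INTEGER, created_utc TEXT
);
CREATE TABLE IF NOT EXISTS frame (
    experiment_id INTEGER REFERENCES experiment(experiment_id),
    frame INTEGER, time_min REAL, height_px INTEGER, width_px INTEGER,
    n_colonies INTEGER, n_cells INTEGER,
    PRIMARY KEY (experiment_id, frame)
);
CREATE TABLE IF NOT EXISTS colony (
    experiment_id INTEGER REFERENCES experiment(experiment_id),
    frame INTEGER, colony_track_id INTEGER,
    area_px INTEGER, area_um2 REAL,
    centroid_row REAL, centroid_col REAL, cell_count INTEGER, event TEXT,
    PRIMARY KEY (experiment_id, frame, colony_track_id)
);
CREATE TABLE IF NOT EXISTS cell_instant (
    experiment_id INTEGER REFERENCES experiment(experiment_id),
    cell_instant_id INTEGER, cell_id INTEGER, frame INTEGER,
    colony_track_id INTEGER,
    centroid_row REAL, centroid_col REAL, area_px INTEGER, area_um2 REAL,
    length_um REAL, width_um REAL, orientation REAL,
    dist_to_colony_centroid_um REAL,
    fluor_total REAL, fluor_mean REAL, on_colony_boundary INTEGER,
    PRIMARY KEY (experiment_id, frame, cell_instant_id)
);
CREATE TABLE IF NOT EXISTS cell (
    experiment_id INTEGER REFERENCES experiment(experiment_id),
    cell_id INTEGER, parent_cell_id INTEGER, colony_track_id INTEGER,
    birth_frame INTEGER, division_frame INTEGER, fate TEXT,
    generation INTEGER, n_instants INTEGER,
    T_div_min REAL, l0_um REAL, lf_um REAL,
    k_per_min REAL, elongation_E REAL, censored INTEGER,
    mean_length_um REAL, max_area_um2 REAL,
    PRIMARY KEY (experiment_id, cell_id)
);
"""


@dataclass
class ExperimentRecord:
    experiment_id: int = 1
    description: str = ""
    modality: str = "phase-contrast"
    species: str = ""
    cell_length_um: float = 3.5
    cell_width_um: float = 1.1
    cal_factor: float = 0.125
    sampling_period_min: float = 5.0
    pipeline_version: str = "0.1.0"
    rng_seed: int = 0
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds"))

    def as_row(self) -> dict:
        return self.__dict__.copy()


def export_database(out_dir: str | Path, experiment: ExperimentRecord,
                    frame_df: pd.DataFrame | None = None,
                    colony_df: pd.DataFrame | None = None,
                    cell_instant_df: pd.DataFrame | None = None,
                    cell_df: pd.DataFrame | None = None,
                    db_name: str = "results.sqlite") -> Path:
    """Write SQLite plus CSV mirrors; partial runs produce partial tables.

    Deterministic: given identical inputs, the CSVs are byte-identical (the
    experiment timestamp lives only in the experiment table and is set by the
    caller via ``ExperimentRecord``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db_path = out / db_name
    db_path.unlink(missing_ok=True)  # re-export replaces, idempotently
    con = sqlite3.connect(db_path)
    try:
        con.execute("PRAGMA foreign_keys = ON")
        con.executescript(_SCHEMA)
        exp_df = pd.DataFrame([experiment.as_row()])
        tables = {"experiment": exp_df, "frame": frame_df, "colony": colony_df,
                  "cell_instant": cell_instant_df, "cell": cell_df}
        for name, df in tables.items():
            if df is None:
                df = pd.DataFrame()
            else:
                df = df.copy()
                if "experiment_id" not in df.columns and not df.empty:
                    df.insert(0, "experiment_id", experiment.experiment_id)
                df.to_sql(name, con, if_exists="append", index=False)
            df.to_csv(out / f"{name}.csv", index=False)
        con.commit()
    finally:
        con.close()
    return db_path


def foreign_key_audit(db_path: str | Path) -> list[str]:
    """Referential-integrity audit; returns a list of violations (empty = ok)."""
    con = sqlite3.connect(db_path)
    try:
        problems = [f"fk:{row}" for row in con.execute("PRAGMA foreign_key_check")]
        cur = con.execute("""
            SELECT COUNT(*) FROM cell_instant ci
            LEFT JOIN cell c ON ci.cell_id = c.cell_id
                AND ci.experiment_id = c.experiment_id
            WHERE ci.cell_id IS NOT NULL AND c.cell_id IS NULL""")
        orphans = cur.fetchone()[0]
        if orphans:
            problems.append(f"{orphans} cell_instant rows reference missing cells")
        cur = con.execute("""
            SELECT COUNT(*) FROM cell_instant ci
            LEFT JOIN frame f ON ci.frame = f.frame
                AND ci.experiment_id = f.experiment_id
            WHERE f.frame IS NULL""")
        missing = cur.fetchone()[0]
        if missing:
            problems.append(f"{missing} cell_instant rows reference missing frames")
        return problems
    finally:
        con.close()
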
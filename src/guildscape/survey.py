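"""Point-count observation records, guilds and the level of persistence (LOP).

A guild is characterized by exactly three bird species.  At each survey a
plot scores 0..3 for a guild — the number of its species recorded present
(abundance is deliberately ignored).  The LOP of a plot for a guild is the
sum of these scores over every survey of the design, so its range is
[0, 3 * S] with S the total number of surveys; the four-year design with
visit counts (5, 5, 5, 4) gives the familiar maximum of 57.

Records are presence-only: a (plot, survey, species) row means the species
was seen; absence is implicit.  An optional count column is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["plot_id", "year", "visit", "species_code"]


@dataclass(frozen=True)
class Guild:
    guild_id: str
    species: tuple

    def __post_init__(self):
        if len(self.species) != 3 or len(set(self.species)) != 3:
            raise ValueError("a guild is exactly 3 distinct species")


@dataclass
class SurveyDesign:
    """Years surveyed and visits per year, e.g. the (5, 5, 5, 4) design."""

    years: list
    visits_per_year: list

    def __post_init__(self):
        if len(self.years) != len(self.visits_per_year):
            raise ValueError("years and visit counts must align")
        if any(v < 1 for v in self.visits_per_year):
            raise ValueError("every year needs at least one visit")

    @property
    def total_surveys(self):
        return int(sum(self.visits_per_year))

    def survey_ids(self):
        return [(y, v + 1) for y, nv in zip(self.years, self.visits_per_year)
                for v in range(nv)]


#: four seasons, five visits each except a four-visit final year
DEFAULT_DESIGN = SurveyDesign([1999, 2000, 2001, 2002], [4, 5, 5, 5])


def normalize_records(records):
    """Coerce a record table to the canonical presence-only form.

    Accepts a DataFrame with at least plot_id,year,visit,species_code;
    duplicate rows collapse to one presence; any count column is dropped.
    """
    df = pd.DataFrame(records)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table lacks columns {missing}")
    return df[RECORD_COLUMNS].drop_duplicates().reset_index(drop=True)


def survey_presence_count(records, guild, plot_id, survey_id):
    """Number of guild species (0..3) present at one plot on one survey."""
    year, visit = survey_id
    df = normalize_records(records)
    sel = df[(df.plot_id == plot_id) & (df.year == year) & (df.visit == visit)]
    return int(sel.species_code.isin(guild.species).sum())


def compute_lop(records, guild, plot_id, design=DEFAULT_DESIGN):
    """Level of persistence: summed guild presence counts over all surveys."""
    df = normalize_records(records)
    df = df[(df.plot_id == plot_id) & df.species_code.isin(guild.species)]
    valid = set(design.survey_ids())
    n = int(sum(1 for _, r in df.iterrows() if (r.year, r.visit) in valid))
    return n


def lop_table(records, guilds, plots, design=DEFAULT_DESIGN,
              strict_coverage=False, surveyed=None):
    """Plot x guild LOP matrix.

    With ``strict_coverage``, plots not visited at every survey of the
    design are dropped (mirrors excluding incompletely covered stations);
    coverage is taken from ``surveyed``, a table of (plot_id, year, visit)
    visits actually made — when absent, the presence records themselves.
    """
    if not guilds:
        raise ValueError("no guilds given")
    if not plots:
        raise ValueError("no plots given")
    df = normalize_records(records)
    valid = set(design.survey_ids())
    df = df[[((y, v) in valid) for y, v in zip(df.year, df.visit)]]

    plot_ids = [p if isinstance(p, str) else p.plot_id for p in plots]
    if strict_coverage:
        cov_df = normalize_records(surveyed)[["plot_id", "year", "visit"]] \
            if surveyed is not None else df
        covered = cov_df.groupby("plot_id").apply(
            lambda s: valid <= set(zip(s.year, s.visit)), include_groups=False)
        kept = [p for p in plot_ids if covered.get(p, False)]
        dropped = sorted(set(plot_ids) - set(kept))
        if dropped:
            logger.warning("dropping %d plots with incomplete survey coverage: %s",
                           len(dropped), dropped)
        plot_ids = kept

    table = pd.DataFrame(0, index=pd.Index(plot_ids, name="plot_id"),
                         columns=[g.guild_id for g in guilds], dtype=int)
    for g in guilds:
        sub = df[df.species_code.isin(g.species)]
        counts = sub.groupby("plot_id").size()
        for pid in plot_ids:
            table.loc[pid, g.guild_id] = int(counts.get(pid, 0))
    table.attrs["design"] = design
    bound = 3 * design.total_surveys
    assert ((table >= 0) & (table <= bound)).all().all()
    return table


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_observations_csv(path):
    """Observation CSV: plot_id,year,visit,species_code[,count]."""
    df = pd.read_csv(path, dtype={"plot_id": str, "species_code": str})
    return normalize_records(df)


def write_observations_csv(path, records):
    normalize_records(records).to_csv(path, index=False)


def read_guilds(path):
    """Guild config (YAML or JSON): mapping guild_id -> [3 species codes]."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [Guild(gid, tuple(sp)) for gid, sp in data.items()]


def write_lop_csv(path, table):
    table.to_csv(path)
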
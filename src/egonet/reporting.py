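"""Tabulation and end-to-end reporting.

Produces the study's table shapes as pandas DataFrames:

* actor descriptives — counts and percentages per attribute level, by role
  (and by site for alters), plus per-network alter-age mean +- SD;
* per-network metrics — ties, density, degrees, normalized betweenness,
  centralization, injectable-user count;
* E-I indices — one row per network, two columns (both groups) per attribute,
  with the en dash for undefined cells;
* homophily sources — homophilic egos/alters/total per attribute.

``run_report`` glues generation-or-ingestion, metrics, tables and sociogram
export together and writes everything under one output directory together
with a provenance log (seed, config hash, package version).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import metrics as m
from .model import StudyCollection
from .scheme import EI_ATTRIBUTES, HOMOPHILY_ATTRIBUTES
from .sociogram import export_sociogram
from .synth import GeneratorConfig, generate_study
from .io import read_study, write_study

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """All tables of one analysis run."""

    descriptives: pd.DataFrame
    ages: pd.DataFrame
    relationships: pd.DataFrame
    network_metrics: pd.DataFrame
    ei_table: pd.DataFrame
    homophily: pd.DataFrame

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "descriptives": self.descriptives,
            "ages": self.ages,
            "relationships": self.relationships,
            "network_metrics": self.network_metrics,
            "ei_indices": self.ei_table,
            "homophily": self.homophily,
        }


# ---------------------------------------------------------------------------
# descriptive tables


def tabulate_descriptives(collection: StudyCollection) -> pd.DataFrame:
    """Counts/percentages per attribute level for egos, alters and all actors."""
    rows: List[Dict[str, object]] = []
    egos, alters = collection.egos, collection.alters
    n_e, n_a = len(egos), len(alters)
    for name in collection.scheme.names:
        levels = collection.scheme.levels(name)
        # denominators exclude NA (e.g. marriage type among married actors only)
        def_e = sum(a.get(name) is not None for a in egos)
        def_a = sum(a.get(name) is not None for a in alters)
        for level in levels:
            c_e = sum(a.get(name) == level for a in egos)
            c_a = sum(a.get(name) == level for a in alters)
            rows.append(
                {
                    "attribute": name,
                    "level": level,
                    "ego_n": c_e,
                    "ego_pct": m.round1(100.0 * c_e / def_e) if def_e else 0.0,
                    "alter_n": c_a,
                    "alter_pct": m.round1(100.0 * c_a / def_a) if def_a else 0.0,
                    "total_n": c_e + c_a,
                    "total_pct": (
                        m.round1(100.0 * (c_e + c_a) / (def_e + def_a))
                        if def_e + def_a
                        else 0.0
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "attribute", "level", "ego_n", "ego_pct",
            "alter_n", "alter_pct", "total_n", "total_pct",
        ],
    )


def tabulate_ages(collection: StudyCollection) -> pd.DataFrame:
    """Per network: ego age and alter-age mean +- SD (sample SD, ddof=1)."""
    rows = []
    for net in collection:
        ages = pd.Series([a.age for a in net.alters], dtype=float).dropna()
        rows.append(
            {
                "network": net.label,
                "site": net.site,
                "ego_age": net.ego.age,
                "alter_age_mean": m.round1(ages.mean()) if len(ages) else None,
                "alter_age_sd": (
                    m.round1(ages.std(ddof=1)) if len(ages) > 1 else None
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["network", "site", "ego_age", "alter_age_mean", "alter_age_sd"]
    )


RELATIONSHIP_ATTRS = ("relationship", "interaction_place", "interaction_freq")


def tabulate_relationships(collection: StudyCollection) -> pd.DataFrame:
    """Alters' relation to ego by site: counts and within-site percentages."""
    rows = []
    site_a = [a for n in collection if n.site == "A" for a in n.alters]
    site_b = [a for n in collection if n.site == "B" for a in n.alters]
    n_a, n_b = len(site_a), len(site_b)
    for name in RELATIONSHIP_ATTRS:
        if name not in collection.scheme.attributes:
            continue
        for level in collection.scheme.levels(name):
            c_a = sum(x.get(name) == level for x in site_a)
            c_b = sum(x.get(name) == level for x in site_b)
            rows.append(
                {
                    "attribute": name,
                    "level": level,
                    "site_a_n": c_a,
                    "site_a_pct": m.round1(100.0 * c_a / n_a) if n_a else 0.0,
                    "site_b_n": c_b,
                    "site_b_pct": m.round1(100.0 * c_b / n_b) if n_b else 0.0,
                    "total_n": c_a + c_b,
                    "total_pct": (
                        m.round1(100.0 * (c_a + c_b) / (n_a + n_b))
                        if n_a + n_b
                        else 0.0
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "attribute", "level", "site_a_n", "site_a_pct",
            "site_b_n", "site_b_pct", "total_n", "total_pct",
        ],
    )


# ---------------------------------------------------------------------------
# metric tables


def tabulate_network_metrics(collection: StudyCollection) -> pd.DataFrame:
    return pd.DataFrame([m.network_summary(net).rounded() for net in collection])


def tabulate_ei(
    collection: StudyCollection,
    attributes: Sequence[str] = EI_ATTRIBUTES,
) -> pd.DataFrame:
    """Per-network E-I indices, both groups per attribute; NA as en dash."""
    rows = []
    for net in collection:
        row: Dict[str, object] = {"network": net.label, "site": net.site}
        for attr in attributes:
            for group in collection.scheme.binary_groups(attr):
                res = m.group_ei_index(net, attr, group, collection.scheme)
                row[f"{attr}:{group}"] = res.render()
        rows.append(row)
    return pd.DataFrame(rows)


def tabulate_homophily(
    collection: StudyCollection,
    attributes: Sequence[str] = HOMOPHILY_ATTRIBUTES,
    threshold: float = 0.0,
) -> pd.DataFrame:
    rows = []
    for attr in attributes:
        s = m.homophily_summary(collection, attr, threshold=threshold)
        rows.append(
            {
                "attribute": attr,
                "ego_n": s.ego_count,
                "ego_pct": s.ego_pct,
                "alter_n": s.alter_count,
                "alter_pct": s.alter_pct,
                "total_n": s.total_count,
                "total_pct": s.total_pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "attribute", "ego_n", "ego_pct", "alter_n", "alter_pct",
            "total_n", "total_pct",
        ],
    )


def build_report(
    collection: StudyCollection, homophily_threshold: float = 0.0
) -> ReportBundle:
    return ReportBundle(
        descriptives=tabulate_descriptives(collection),
        ages=tabulate_ages(collection),
        relationships=tabulate_relationships(collection),
        network_metrics=tabulate_network_metrics(collection),
        ei_table=tabulate_ei(collection),
        homophily=tabulate_homophily(collection, threshold=homophily_threshold),
    )


# ---------------------------------------------------------------------------
# end-to-end


def run_report(
    out_dir: str | Path,
    collection: Optional[StudyCollection] = None,
    config: Optional[GeneratorConfig] = None,
    roster_path: Optional[str | Path] = None,
    ties_path: Optional[str | Path] = None,
    sociogram_format: str = "graphml",
    homophily_threshold: float = 0.0,
) -> ReportBundle:
    """Run the full pipeline and write tables, sociograms and a run log.

    Exactly one input source: an in-memory collection, a generator config
    (synthetic study), or roster+ties paths.
    """
    sources = sum(
        x is not None for x in (collection, config, roster_path)
    )
    if sources != 1:
        raise ValueError(
            "provide exactly one of collection, config, or roster_path(+ties_path)"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_lines = [f"egonet {__version__}"]
    if config is not None:
        collection = generate_study(config)
        cfg_yaml = yaml.safe_dump(
            {
                "seed": config.seed,
                "k_egos": config.k_egos,
                "n_alters": config.n_alters,
                "base_tie_prob": config.base_tie_prob,
                "homophily_weights": dict(config.homophily_weights),
                "site_split": config.site_split,
                "attribute_marginals": {
                    k: dict(v) for k, v in config.attribute_marginals.items()
                },
            },
            sort_keys=True,
        )
        (out_dir / "config.yaml").write_text(cfg_yaml, encoding="utf-8")
        log_lines.append(f"seed: {config.seed}")
        log_lines.append(
            "config_sha256: " + hashlib.sha256(cfg_yaml.encode()).hexdigest()
        )
        write_study(collection, out_dir / "roster.csv", out_dir / "ties.csv")
    elif roster_path is not None:
        if ties_path is None:
            raise ValueError("ties_path is required with roster_path")
        collection = read_study(roster_path, ties_path)
        log_lines.append(f"roster: {roster_path}")
        log_lines.append(f"ties: {ties_path}")

    assert collection is not None
    bundle = build_report(collection, homophily_threshold=homophily_threshold)
    for name, df in bundle.tables().items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    soc_dir = out_dir / "sociograms"
    soc_dir.mkdir(exist_ok=True)
    ext = "graphml" if sociogram_format == "graphml" else "dot"
    for net in collection:
        export_sociogram(net, soc_dir / f"{net.label}.{ext}", fmt=sociogram_format)
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    logger.info("report written to %s (%d networks)", out_dir, len(collection))
    return bundle
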
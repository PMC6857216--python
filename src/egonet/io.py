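"""Reading and writing questionnaire-derived network data.

Two plain-text artefacts describe a study:

* a **roster** CSV — one row per actor with columns ``network_label, site,
  actor_id, role, age`` and one column per scheme attribute (empty cell = NA);
* **ties** — either one edge-list CSV (``network_label, actor_id_1,
  actor_id_2``) or a directory of per-network square 0/1 adjacency matrices
  (``<label>.csv`` with actor ids as header row and first column).

Matrices are parsed leniently on symmetry: an entry reported in only one
direction still yields a tie (OR-symmetrization) with a logged warning, since
ego-reported alter-alter relations are frequently one-sided.  Write then read
round-trips to an identical collection.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    Actor,
    EgoNetwork,
    StudyCollection,
    ValidationError,
    build_network,
)
from .scheme import AttributeScheme, default_scheme

logger = logging.getLogger(__name__)

ROSTER_FIXED_COLUMNS = ["network_label", "site", "actor_id", "role", "age"]
EDGE_COLUMNS = ["network_label", "actor_id_1", "actor_id_2"]


class FormatError(ValidationError):
    """Malformed roster/tie file; the message carries file and line context."""


def _fmt_err(path: Path, line: Optional[int], msg: str) -> FormatError:
    where = f"{path}" if line is None else f"{path}:{line}"
    return FormatError(f"{where}: {msg}")


# ---------------------------------------------------------------------------
# writing


def write_study(
    collection: StudyCollection,
    roster_path: str | Path,
    ties_path: str | Path,
) -> None:
    """Write roster + edge-list CSVs (byte-stable given fixed column order)."""
    roster_path, ties_path = Path(roster_path), Path(ties_path)
    scheme = collection.scheme
    with roster_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_FIXED_COLUMNS + scheme.names)
        for net in collection:
            for actor in net.actors:
                row = [
                    net.label,
                    net.site,
                    actor.actor_id,
                    actor.role,
                    "" if actor.age is None else repr(actor.age),
                ]
                row += [actor.get(name) or "" for name in scheme.names]
                writer.writerow(row)
    with ties_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EDGE_COLUMNS)
        for net in collection:
            for a, b in sorted(net.ties):
                writer.writerow([net.label, a, b])


def write_tie_matrix(network: EgoNetwork, path: str | Path) -> None:
    """Square 0/1 adjacency CSV; actor order = ego first, then alters."""
    path = Path(path)
    ids = network.actor_ids
    adj = network.adjacency()
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + ids)
        for i in ids:
            writer.writerow([i] + [int(j in adj[i]) for j in ids])


def write_study_matrices(collection: StudyCollection, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for net in collection:
        write_tie_matrix(net, directory / f"{net.label}.csv")


# ---------------------------------------------------------------------------
# reading


def _read_roster(
    roster_path: Path, scheme: AttributeScheme
) -> Dict[str, Dict[str, object]]:
    """network label -> {"site": str, "ego": Actor, "alters": [Actor, ...]}"""
    networks: Dict[str, Dict[str, object]] = {}
    with roster_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ROSTER_FIXED_COLUMNS if c not in header]
        if missing:
            raise _fmt_err(roster_path, 1, f"missing columns {missing}")
        attr_cols = [c for c in header if c not in ROSTER_FIXED_COLUMNS]
        unknown = [c for c in attr_cols if c not in scheme.attributes]
        if unknown:
            raise _fmt_err(
                roster_path, 1, f"columns {unknown} are not scheme attributes"
            )
        for lineno, row in enumerate(reader, start=2):
            label = row["network_label"]
            rec = networks.setdefault(
                label, {"site": row["site"], "ego": None, "alters": []}
            )
            attrs = {c: (row[c] or None) for c in attr_cols}
            age = float(row["age"]) if row.get("age") else None
            actor = Actor(
                actor_id=row["actor_id"], role=row["role"], attributes=attrs, age=age
            )
            if actor.role == "ego":
                if rec["ego"] is not None:
                    raise _fmt_err(
                        roster_path, lineno, f"second ego row for network {label!r}"
                    )
                rec["ego"] = actor
            else:
                rec["alters"].append(actor)
    for label, rec in networks.items():
        if rec["ego"] is None:
            raise _fmt_err(roster_path, None, f"network {label!r} has no ego row")
    return networks


def _read_edge_list(path: Path) -> Dict[str, List[Tuple[str, str]]]:
    ties: Dict[str, List[Tuple[str, str]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != EDGE_COLUMNS:
            raise _fmt_err(path, 1, f"expected header {EDGE_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise _fmt_err(path, lineno, f"expected 3 fields, got {len(row)}")
            label, a, b = row
            ties.setdefault(label, []).append((a, b))
    return ties


def read_tie_matrix(path: str | Path) -> Tuple[List[str], List[Tuple[str, str]]]:
    """Parse one adjacency CSV; returns (actor ids, unordered tie pairs).

    One-sided entries are OR-symmetrized with a warning; a non-square matrix
    or an off-header row label is an error.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise _fmt_err(path, None, "empty matrix file")
    ids = [c for c in rows[0][1:]]
    n = len(ids)
    body = rows[1:]
    if len(body) != n or any(len(r) != n + 1 for r in body):
        raise _fmt_err(
            path,
            None,
            f"matrix is not square: header lists {n} actors, "
            f"body has {len(body)} rows of widths {sorted({len(r) for r in body})}",
        )
    cells: Dict[Tuple[int, int], int] = {}
    for i, row in enumerate(body):
        if row[0] != ids[i]:
            raise _fmt_err(
                path, i + 2, f"row label {row[0]!r} does not match header {ids[i]!r}"
            )
        for j, cell in enumerate(row[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise _fmt_err(path, i + 2, f"non-integer cell {cell!r}") from None
            if value not in (0, 1):
                raise _fmt_err(path, i + 2, f"cell must be 0 or 1, got {value}")
            cells[(i, j)] = value
    for i in range(n):
        if cells[(i, i)] != 0:
            raise _fmt_err(path, i + 2, f"non-zero diagonal for actor {ids[i]!r}")
    pairs: List[Tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            upper, lower = cells[(i, j)], cells[(j, i)]
            if upper != lower:
                logger.warning(
                    "%s: asymmetric entry (%s, %s): %d vs %d; keeping the tie",
                    path, ids[i], ids[j], upper, lower,
                )
            if upper or lower:
                pairs.append((ids[i], ids[j]))
    return ids, pairs


def read_study(
    roster_path: str | Path,
    ties_path: str | Path,
    scheme: Optional[AttributeScheme] = None,
) -> StudyCollection:
    """Assemble a validated collection from a roster plus ties.

    ``ties_path`` may be an edge-list CSV or a directory of per-network
    adjacency matrices named ``<label>.csv``.
    """
    scheme = scheme if scheme is not None else default_scheme()
    roster_path, ties_path = Path(roster_path), Path(ties_path)
    if not roster_path.exists():
        raise _fmt_err(roster_path, None, "roster file not found")
    if not ties_path.exists():
        raise _fmt_err(ties_path, None, "ties file or directory not found")
    rosters = _read_roster(roster_path, scheme)

    ties_by_label: Dict[str, List[Tuple[str, str]]] = {}
    if ties_path.is_dir():
        for label, rec in rosters.items():
            matrix = ties_path / f"{label}.csv"
            if not matrix.exists():
                raise _fmt_err(matrix, None, f"no matrix for network {label!r}")
            ids, pairs = read_tie_matrix(matrix)
            declared = [rec["ego"].actor_id] + [a.actor_id for a in rec["alters"]]
            if set(ids) != set(declared):
                raise _fmt_err(
                    matrix, None,
                    f"matrix actors {sorted(ids)} do not match roster "
                    f"{sorted(declared)}",
                )
            ties_by_label[label] = pairs
    else:
        ties_by_label = _read_edge_list(ties_path)
        stray = set(ties_by_label) - set(rosters)
        if stray:
            raise _fmt_err(
                ties_path, None, f"ties for networks missing from roster: {sorted(stray)}"
            )

    networks = [
        build_network(
            label,
            str(rec["site"]),
            rec["ego"],  # type: ignore[arg-type]
            rec["alters"],  # type: ignore[arg-type]
            ties_by_label.get(label, []),
            scheme=scheme,
        )
        for label, rec in rosters.items()
    ]
    return StudyCollection(networks=networks, scheme=scheme)
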
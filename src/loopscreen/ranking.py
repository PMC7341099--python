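"""Structure-based scores and consensus ranking.

Docking logs (AutoDock-Vina-style mode tables, at most nine conformations)
are parsed into per-molecule binding affinities; the structure-based score
of a candidate is the arithmetic mean affinity over its modes (more
negative = better).  The knowledge-based probability ranking and the
structure-based ranking are then combined - by rank sum by default, with
Borda and top-K-intersection alternatives - and candidates high in both
lists are flagged (``dual_high``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

MAX_MODES = 9

_MODE_RE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+\S+\s+\S+\s*$")


class DockingParseError(ValueError):
    """No mode table found in a docking log."""


@dataclass(frozen=True)
class DockingResult:
    molecule_id: str
    modes: tuple[tuple[int, float], ...]
    receptor_tag: str = ""

    @property
    def affinities(self) -> list[float]:
        return [a for _, a in self.modes]


def parse_docking_log(
    text: str, molecule_id: str = "", receptor_tag: str = ""
) -> DockingResult:
    """Parse a Vina-style log: ``mode | affinity | rmsd l.b. | rmsd u.b.``.

    Tolerant of header banners; keeps modes in listed order and caps at
    nine conformations.
    """
    modes = []
    for line in text.splitlines():
        m = _MODE_RE.match(line)
        if m:
            modes.append((int(m.group(1)), float(m.group(2))))
    if not modes:
        raise DockingParseError(
            f"no docking mode table found{' in ' + molecule_id if molecule_id else ''}"
        )
    return DockingResult(
        molecule_id=molecule_id, modes=tuple(modes[:MAX_MODES]), receptor_tag=receptor_tag
    )


def parse_docking_logs(paths, receptor_tag: str = "") -> list[DockingResult]:
    """Parse many logs; the molecule id is the file stem."""
    out = []
    for p in sorted(Path(p) for p in paths):
        out.append(parse_docking_log(p.read_text(), molecule_id=p.stem, receptor_tag=receptor_tag))
    return out


def average_binding_energy(result: DockingResult) -> float:
    """Mean binding affinity over reported modes (kcal/mol)."""
    if not result.modes:
        raise ValueError("docking result has no modes")
    aff = result.affinities
    return sum(aff) / len(aff)


class RankingError(ValueError):
    """Molecule universes of the two score lists differ."""


def combine_rankings(
    kb_scores: pd.DataFrame,
    sb_scores: pd.DataFrame,
    method: str = "ranksum",
    top_k: int = 10,
) -> pd.DataFrame:
    """Consensus ranking of knowledge-based and structure-based scores.

    ``kb_scores``: molecule_id, probability (higher = better).
    ``sb_scores``: molecule_id, mean_affinity (lower = better).
    Returns one row per molecule with kb_rank, sb_rank, combined_rank and
    the ``dual_high`` flag (top-K in both lists).  Ties in the combined
    ordering break on better kb_rank, then molecule_id.
    """
    kb = kb_scores[["molecule_id", "probability"]].copy()
    sb = sb_scores[["molecule_id", "mean_affinity"]].copy()
    kb_ids, sb_ids = set(kb["molecule_id"]), set(sb["molecule_id"])
    if kb_ids != sb_ids:
        missing = sorted(kb_ids ^ sb_ids)
        raise RankingError(f"molecule universes differ; unmatched ids: {missing}")
    kb = kb.sort_values(["probability", "molecule_id"], ascending=[False, True])
    kb["kb_rank"] = range(1, len(kb) + 1)
    sb = sb.sort_values(["mean_affinity", "molecule_id"], ascending=[True, True])
    sb["sb_rank"] = range(1, len(sb) + 1)
    df = kb.merge(sb, on="molecule_id")
    n = len(df)
    if method == "ranksum":
        df["combined_score"] = df["kb_rank"] + df["sb_rank"]
        ascending = True
    elif method == "borda":
        df["combined_score"] = (n - df["kb_rank"]) + (n - df["sb_rank"])
        ascending = False
    elif method == "topk_intersection":
        df["combined_score"] = (
            (df["kb_rank"] <= top_k) & (df["sb_rank"] <= top_k)
        ).astype(int)
        ascending = False
    else:
        raise ValueError(f"unknown combination method {method!r}")
    df = df.sort_values(
        ["combined_score", "kb_rank", "molecule_id"],
        ascending=[ascending, True, True],
    ).reset_index(drop=True)
    df["combined_rank"] = range(1, n + 1)
    df["dual_high"] = (df["kb_rank"] <= top_k) & (df["sb_rank"] <= top_k)
    return df[
        [
            "molecule_id",
            "probability",
            "kb_rank",
            "mean_affinity",
            "sb_rank",
            "combined_rank",
            "dual_high",
        ]
    ]
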
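"""Pathway completeness scoring from KEGG Orthology (KO) annotations.

A pathway rule is an ordered list of requirement groups; each group is a set
of alternative KO ids and is satisfied when the genome carries any member.
The pathway is complete when every group is satisfied. Three rules ship as
packaged data: pyrimidine salvage (thymidine kinase K00857, thymidylate
kinase K00943, nucleoside-diphosphate kinase K00940 — the route that converts
exogenous nucleosides such as thymidine/EdU into nucleotides, and hence is
required for EdU labeling), de novo pyrimidine synthesis (KEGG module M00051,
eight groups, with a dihydroorotate-dehydrogenase OR-group), and pyrimidine
deoxyribonucleoside biosynthesis (KEGG module M00053, six KOs). K00940 and
K00943 legitimately appear in both the salvage and deoxyribonucleoside rules;
rules are evaluated independently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PathwayRule",
    "GenomeAnnotation",
    "builtin_rules",
    "load_rules",
    "read_genome_annotations",
    "score",
    "score_batch",
]

KO_PATTERN = re.compile(r"^K\d{5}$")


@dataclass(frozen=True)
class PathwayRule:
    """Named requirement: a tuple of OR-groups of KO ids."""

    name: str
    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("a rule needs at least one group")
        for g in self.groups:
            if not g:
                raise ValueError("empty requirement group")
            bad = [k for k in g if not KO_PATTERN.match(k)]
            if bad:
                raise ValueError(f"malformed KO ids in rule {self.name!r}: {bad}")

    @property
    def all_kos(self) -> frozenset[str]:
        return frozenset().union(*self.groups)


@dataclass
class GenomeAnnotation:
    """A genome's KO set (duplicates collapse; malformed ids are dropped
    with a warning)."""

    genome_id: str
    kos: frozenset[str]

    def __init__(self, genome_id: str, kos) -> None:
        self.genome_id = genome_id
        valid, bad = set(), []
        for k in kos:
            if KO_PATTERN.match(k):
                valid.add(k)
            else:
                bad.append(k)
        if bad:
            import warnings

            warnings.warn(
                f"genome {genome_id!r}: ignoring malformed KO ids {sorted(set(bad))}"
            )
        self.kos = frozenset(valid)


def _parse_rule_line(line: str) -> PathwayRule:
    name, groups_field = line.split("\t", 1)
    groups = tuple(
        frozenset(alt.strip() for alt in grp.split("|"))
        for grp in groups_field.strip().split(",")
    )
    return PathwayRule(name=name.strip(), groups=groups)


def load_rules(path) -> list[PathwayRule]:
    """Read rules from structured text: ``name<TAB>group,group,...`` with
    pipe-separated alternatives inside each group."""
    rules = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rules.append(_parse_rule_line(line))
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("duplicate rule names in rules file")
    return rules


def builtin_rules() -> list[PathwayRule]:
    """The three packaged pyrimidine pathway rules (3 / 8 / 6 groups)."""
    ref = resources.files("edufacsseq").joinpath("data/pyrimidine_modules.tsv")
    with resources.as_file(ref) as path:
        return load_rules(path)


def read_genome_annotations(path) -> list[GenomeAnnotation]:
    """Read a two-column TSV of ``genome_id<TAB>ko_id`` pairs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genome_id", "ko_id"], comment="#")
    return [
        GenomeAnnotation(gid, set(sub["ko_id"]))
        for gid, sub in df.groupby("genome_id", sort=True)
    ]


def score(genome: GenomeAnnotation, rule: PathwayRule) -> dict:
    """One completeness row: complete iff every group intersects the KO set."""
    satisfied = sum(1 for g in rule.groups if g & genome.kos)
    missing = [sorted(g) for g in rule.groups if not (g & genome.kos)]
    total = len(rule.groups)
    return {
        "genome_id": genome.genome_id,
        "pathway": rule.name,
        "complete": satisfied == total,
        "satisfied_groups": satisfied,
        "total_groups": total,
        "completeness_fraction": satisfied / total,
        "missing_groups": missing,
    }


def score_batch(genomes, rules) -> pd.DataFrame:
    """Completeness report over genomes x rules, in deterministic order."""
    genomes = list(genomes)
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in batch")
    rows = [score(g, r) for g in genomes for r in rules]
    return pd.DataFrame(rows)
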
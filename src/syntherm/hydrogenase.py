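"""Motif-based hydrogenase detection and classification.

Candidate hydrogenases are found by scanning protein sequences with
regular expressions for the conserved metal-binding motifs of the two
enzyme classes ([FeFe]: H-cluster L1/L2/L3; [NiFe]: the two CxxC
nickel-binding motifs).  Group assignment below the metal class relies
on an optional external group column (e.g. an HydDB export), except for
the bifurcating-A3 rule: an [FeFe] type-A hydrogenase within five coding
sequences of a NuoF gene on the same contig is called "FeFe A3", since
NuoF provides the NADH-binding module these electron-bifurcating
complexes require.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Inclusive CDS-distance bound of the NuoF proximity rule.
A3_MAX_DISTANCE = 5

DEFAULT_NUOF_PATTERN = r"nuoF"


class HydrogenaseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    """One coding sequence with its position along a contig."""

    gene_id: str
    contig_id: str
    ordinal: int  # 0-based CDS index along the contig
    product_label: str = ""
    protein_sequence: str = ""

    def __post_init__(self) -> None:
        bad = set(self.protein_sequence) - set(AA_ALPHABET + "X*")
        if bad:
            raise HydrogenaseError(
                f"gene {self.gene_id!r}: invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class MotifRule:
    """A metal-binding-motif regex with its metal class and provenance."""

    name: str
    metal_class: str  # "FeFe" or "NiFe"
    pattern: str
    group_hint: str = ""
    source: str = ""

    def compiled(self) -> re.Pattern:
        try:
            return re.compile(self.pattern)
        except re.error as exc:
            raise HydrogenaseError(f"rule {self.name!r}: invalid regex ({exc})") from exc


@dataclass
class HydrogenaseCall:
    """Classification of one gene: metal class, group, and evidence."""

    gene_id: str
    metal_class: str  # "FeFe", "NiFe" or "ambiguous"
    group: str | None = None  # HydDB-style, e.g. "FeFe A3", "NiFe 1a"
    motif_hits: list[tuple[str, int, int]] = field(default_factory=list)
    proximity_evidence: tuple[str, int] | None = None  # (nuoF gene_id, distance)


def load_motif_rules(path=None) -> list[MotifRule]:
    """Load a motif rule table (TSV); defaults to the bundled canonical set."""
    if path is None:
        with resources.as_file(
            resources.files("syntherm.data") / "hydrogenase_motifs.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t").fillna("")
    else:
        df = pd.read_csv(path, sep="\t").fillna("")
    rules = []
    for row in df.itertuples(index=False):
        rule = MotifRule(
            name=row.name,
            metal_class=row.metal_class,
            pattern=row.pattern,
            group_hint=getattr(row, "group_hint", ""),
            source=getattr(row, "source", ""),
        )
        rule.compiled()  # validate at load, naming the rule on failure
        rules.append(rule)
    return rules


def read_proteome(fasta_path, gene_order_path) -> list[GeneRecord]:
    """Read protein FASTA (headers = gene ids) plus the gene-order TSV
    (columns gene_id, contig, ordinal, product)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    order = pd.read_csv(gene_order_path, sep="\t")
    records = []
    for row in order.itertuples(index=False):
        if row.gene_id not in seqs:
            raise HydrogenaseError(f"gene {row.gene_id!r} missing from FASTA")
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                contig_id=str(row.contig),
                ordinal=int(row.ordinal),
                product_label=str(row.product),
                protein_sequence=seqs[row.gene_id],
            )
        )
    return records


def scan_motifs(
    records: Iterable[GeneRecord], rules: Iterable[MotifRule]
) -> list[HydrogenaseCall]:
    """One call per record matching at least one motif rule.

    Records hit by rules of both metal classes are flagged "ambiguous"
    with both hit sets rather than silently assigned to either class.
    """
    compiled = [(rule, rule.compiled()) for rule in rules]
    calls = []
    for rec in records:
        hits: list[tuple[str, int, int]] = []
        classes: set[str] = set()
        hints: set[str] = set()
        for rule, rx in compiled:
            for match in rx.finditer(rec.protein_sequence):
                hits.append((rule.name, match.start(), match.end()))
                classes.add(rule.metal_class)
                if rule.group_hint:
                    hints.add(f"{rule.metal_class} {rule.group_hint}")
        if not hits:
            continue
        if len(classes) > 1:
            calls.append(
                HydrogenaseCall(gene_id=rec.gene_id, metal_class="ambiguous",
                                motif_hits=hits)
            )
            continue
        metal = classes.pop()
        group = None
        class_hints = {h for h in hints if h.startswith(metal)}
        if len(class_hints) == 1:
            group = class_hints.pop()
        calls.append(
            HydrogenaseCall(gene_id=rec.gene_id, metal_class=metal, group=group,
                            motif_hits=hits)
        )
    return calls


def apply_group_labels(
    calls: Iterable[HydrogenaseCall], groups: Mapping[str, str]
) -> list[HydrogenaseCall]:
    """Refine calls with an external group column (e.g. an HydDB export).

    Only groups consistent with the called metal class are applied;
    inconsistent labels are logged and ignored.
    """
    out = []
    for call in calls:
        group = groups.get(call.gene_id)
        if group is None:
            out.append(replace(call))
            continue
        if call.metal_class != "ambiguous" and not group.startswith(call.metal_class):
            logger.warning(
                "gene %s: external group %r conflicts with motif class %s; ignored",
                call.gene_id, group, call.metal_class,
            )
            out.append(replace(call))
            continue
        out.append(replace(call, group=group))
    return out


def assign_a3_by_proximity(
    calls: Iterable[HydrogenaseCall],
    records: Iterable[GeneRecord],
    nuof_pattern: str = DEFAULT_NUOF_PATTERN,
    max_distance: int = A3_MAX_DISTANCE,
) -> list[HydrogenaseCall]:
    """Upgrade [FeFe] type-A calls near a NuoF gene to bifurcating A3.

    "Near" means an inclusive ordinal distance <= ``max_distance`` on the
    same contig, strand-agnostic.  NuoF genes are identified by a
    case-insensitive product-label match.  Idempotent; with no NuoF in
    the annotation the calls pass through unchanged.
    """
    recs = {r.gene_id: r for r in records}
    rx = re.compile(nuof_pattern, re.IGNORECASE)
    nuof_by_contig: dict[str, list[GeneRecord]] = {}
    for r in recs.values():
        if rx.search(r.product_label):
            nuof_by_contig.setdefault(r.contig_id, []).append(r)
    if not nuof_by_contig:
        logger.info("no NuoF genes found in annotation; A3 rule not applied")
        return [replace(c) for c in calls]

    out = []
    for call in calls:
        new = replace(call)
        is_type_a = call.metal_class == "FeFe" and (
            call.group is None or call.group.startswith("FeFe A")
        )
        if is_type_a:
            rec = recs.get(call.gene_id)
            if rec is not None:
                best: tuple[int, str] | None = None
                for nuof in nuof_by_contig.get(rec.contig_id, ()):
                    d = abs(rec.ordinal - nuof.ordinal)
                    if d <= max_distance and (best is None or d < best[0]):
                        best = (d, nuof.gene_id)
                if best is not None:
                    new.group = "FeFe A3"
                    new.proximity_evidence = (best[1], best[0])
        out.append(new)
    return out


def summarize_repertoire(
    calls: Iterable[HydrogenaseCall], genome_of: Mapping[str, str]
) -> pd.DataFrame:
    """Dense genome x group count table, zero-filled, lexicographic order.

    Calls without a refined group are counted under their metal class.
    """
    rows = []
    for call in calls:
        if call.gene_id not in genome_of:
            raise HydrogenaseError(f"gene {call.gene_id!r} mapped to no genome")
        rows.append((genome_of[call.gene_id], call.group or call.metal_class))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["genome", "group"])
    table = df.groupby(["genome", "group"]).size().unstack(fill_value=0)
    return table.sort_index(axis=0).sort_index(axis=1)


def calls_to_frame(calls: Iterable[HydrogenaseCall]) -> pd.DataFrame:
    """Tidy table of calls for TSV output."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "metal_class": c.metal_class,
                "group": c.group or "",
                "motif_hits": ";".join(f"{n}@{s}-{e}" for n, s, e in c.motif_hits),
                "nuof_gene": c.proximity_evidence[0] if c.proximity_evidence else "",
                "nuof_distance": c.proximity_evidence[1] if c.proximity_evidence else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "metal_class", "group", "motif_hits", "nuof_gene",
                 "nuof_distance"],
    )
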
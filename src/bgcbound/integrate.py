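"""Consensus boundary calling from three evidence streams.

The comparative-genomics span, the regulator-knockout expression classes
and the gene-knockout metabolite phenotypes often disagree at cluster
borders: a border gene may be activated by the pathway regulator yet be
dispensable for pigment production, while genes deep inside the cluster
can escape the regulator entirely.  The consensus rules encode a strict
evidence precedence — knockout > comparative genomics > transcription:

R1  members start as the comparative-genomics span;
R2  outward walk: a gene adjacent to the span joins only on functional
    knockout evidence (abolished / shunt / ratio_shift) — transcriptional
    regulation alone never admits a gene; each side stops at its first
    non-admitted gene;
R3  inward trim: an edge member is dropped only when its knockout is
    neutral AND it is transcriptionally unresponsive (unchanged or not
    expressed); repeated until stable;
R4  interior members are always retained, whatever their evidence.

Missing evidence is representable and is never treated as "unchanged".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .expression import ExpressionResult, RegClass
from .knockout import KnockoutCategory, KnockoutPhenotype


class IntegrationError(ValueError):
    pass


#: knockout categories that count as functional support for membership
_KO_SUPPORT = {KnockoutCategory.ABOLISHED, KnockoutCategory.SHUNT, KnockoutCategory.RATIO_SHIFT}
_KO_STRONG = {KnockoutCategory.ABOLISHED, KnockoutCategory.SHUNT}
_REGULATED = {RegClass.ABOLISHED, RegClass.DOWNREGULATED, RegClass.UPREGULATED}
_UNRESPONSIVE = {RegClass.UNCHANGED, RegClass.NOT_EXPRESSED}


@dataclass
class GeneEvidence:
    gene: str
    in_cg_span: bool = False
    reg_class: Optional[RegClass] = None
    ko_category: Optional[KnockoutCategory] = None


@dataclass
class EvidenceTable:
    """Per-gene evidence in locus order; the cg span must be one contiguous run."""

    rows: list[GeneEvidence]

    def __post_init__(self) -> None:
        flags = [r.in_cg_span for r in self.rows]
        if any(flags):
            first = flags.index(True)
            last = len(flags) - 1 - flags[::-1].index(True)
            if not all(flags[first : last + 1]):
                raise IntegrationError("cg span flags are not contiguous")

    def __len__(self) -> int:
        return len(self.rows)

    def genes(self) -> list[str]:
        return [r.gene for r in self.rows]

    def cg_span_indices(self) -> Optional[tuple[int, int]]:
        flags = [r.in_cg_span for r in self.rows]
        if not any(flags):
            return None
        first = flags.index(True)
        last = len(flags) - 1 - flags[::-1].index(True)
        return first, last


def build_evidence(locus_genes: list[str],
                   cg_members: list[str],
                   expression: Optional[list[ExpressionResult]] = None,
                   ko_by_gene: Optional[dict[str, KnockoutCategory]] = None) -> EvidenceTable:
    """Assemble the evidence table for genes in locus order."""
    reg = {r.gene: r.reg_class for r in (expression or [])}
    ko = dict(ko_by_gene or {})
    cg = set(cg_members)
    rows = [
        GeneEvidence(gene=g, in_cg_span=g in cg,
                     reg_class=reg.get(g), ko_category=ko.get(g))
        for g in locus_genes
    ]
    return EvidenceTable(rows)


@dataclass
class BGCCall:
    """The consensus cluster call with per-gene evidence summary."""

    members: list[str]
    excluded: list[dict] = field(default_factory=list)  # {gene, reason}
    tiers: dict[str, str] = field(default_factory=dict)
    evidence: Optional[EvidenceTable] = None

    @property
    def first_gene(self) -> str:
        return self.members[0]

    @property
    def last_gene(self) -> str:
        return self.members[-1]

    @property
    def n_genes(self) -> int:
        return len(self.members)


def _ko_supported(row: GeneEvidence) -> bool:
    return row.ko_category in _KO_SUPPORT


def _tier(row: GeneEvidence) -> str:
    regulated = row.reg_class in _REGULATED
    if row.in_cg_span and (regulated or row.ko_category in _KO_STRONG):
        return "strong"
    if row.in_cg_span and row.ko_category is KnockoutCategory.RATIO_SHIFT:
        return "weak"
    if row.in_cg_span:
        return "retained-interior"
    # admitted by the outward walk, on knockout evidence alone
    return "strong" if row.ko_category in _KO_STRONG else "weak"


def _exclusion_reason(row: GeneEvidence, was_trimmed: bool) -> str:
    if was_trimmed:
        return "trimmed-ko-neutral-unregulated"
    if row.reg_class in _REGULATED and row.ko_category is KnockoutCategory.UNCHANGED:
        return "regulated-but-ko-neutral"
    if row.ko_category is KnockoutCategory.UNCHANGED:
        return "ko-neutral"
    return "no-supporting-evidence"


def call_bgc(evidence: EvidenceTable) -> BGCCall:
    """Apply the consensus rules R1-R4 and emit the final cluster call."""
    span = evidence.cg_span_indices()
    if span is None:
        raise IntegrationError(
            "no comparative-genomics span in the evidence table: "
            "run the boundary stage first"
        )
    rows = evidence.rows
    lo, hi = span

    # R2: outward walk on knockout support only
    while lo > 0 and _ko_supported(rows[lo - 1]):
        lo -= 1
    while hi < len(rows) - 1 and _ko_supported(rows[hi + 1]):
        hi += 1

    # R3: inward trim of evidence-free edges (ko neutral AND unresponsive)
    trimmed: set[str] = set()

    def trimmable(row: GeneEvidence) -> bool:
        return (row.ko_category is KnockoutCategory.UNCHANGED
                and row.reg_class in _UNRESPONSIVE)

    changed = True
    while changed and lo <= hi:
        changed = False
        if lo <= hi and trimmable(rows[lo]):
            trimmed.add(rows[lo].gene)
            lo += 1
            changed = True
        if lo <= hi and trimmable(rows[hi]):
            trimmed.add(rows[hi].gene)
            hi -= 1
            changed = True
    if lo > hi:
        raise IntegrationError("all candidate members were trimmed away")

    members = [r.gene for r in rows[lo : hi + 1]]
    member_set = set(members)
    tiers = {r.gene: _tier(r) for r in rows[lo : hi + 1]}
    # report non-members that carry some evidence (border genes); genes with
    # no evidence at all are plain background and stay out of the report
    excluded = [
        {"gene": r.gene, "reason": _exclusion_reason(r, r.gene in trimmed)}
        for r in rows
        if r.gene not in member_set
        and (r.in_cg_span or r.reg_class is not None or r.ko_category is not None)
    ]
    return BGCCall(members=members, excluded=excluded, tiers=tiers, evidence=evidence)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def call_to_dict(call: BGCCall) -> dict:
    ev = {}
    if call.evidence is not None:
        for r in call.evidence.rows:
            ev[r.gene] = {
                "in_cg_span": r.in_cg_span,
                "reg_class": r.reg_class.value if r.reg_class else None,
                "ko_category": r.ko_category.value if r.ko_category else None,
                "tier": call.tiers.get(r.gene, "excluded"),
            }
    return {
        "call": {
            "first_gene": call.first_gene,
            "last_gene": call.last_gene,
            "n_genes": call.n_genes,
            "members": list(call.members),
        },
        "excluded": list(call.excluded),
        "evidence": ev,
    }


def call_from_dict(doc: dict) -> BGCCall:
    ev_rows = []
    for gene, e in doc.get("evidence", {}).items():
        ev_rows.append(GeneEvidence(
            gene=gene,
            in_cg_span=bool(e["in_cg_span"]),
            reg_class=RegClass(e["reg_class"]) if e["reg_class"] else None,
            ko_category=KnockoutCategory(e["ko_category"]) if e["ko_category"] else None,
        ))
    tiers = {g: e["tier"] for g, e in doc.get("evidence", {}).items()
             if g in set(doc["call"]["members"])}
    return BGCCall(
        members=list(doc["call"]["members"]),
        excluded=list(doc["excluded"]),
        tiers=tiers,
        evidence=EvidenceTable(ev_rows) if ev_rows else None,
    )


def render_report(call: BGCCall,
                  boundary: Optional[dict] = None,
                  expression: Optional[list[ExpressionResult]] = None,
                  phenotypes: Optional[dict[str, KnockoutPhenotype]] = None,
                  params: Optional[dict] = None) -> dict:
    """Single JSON-ready report with a per-gene evidence matrix.

    Raises when the expression results name genes absent from the evidence
    table (namespace mismatch), listing the orphans.
    """
    doc = call_to_dict(call)
    if call.evidence is not None and expression is not None:
        known = set(call.evidence.genes())
        orphans = sorted({r.gene for r in expression} - known)
        if orphans:
            raise IntegrationError(f"expression results name unknown genes: {orphans}")
    if boundary is not None:
        doc["boundary"] = boundary
    if expression is not None:
        doc["expression"] = [
            {"gene": r.gene, "fold_change": r.fold_change,
             "p_value": r.p_value, "reg_class": r.reg_class.value}
            for r in expression
        ]
    if phenotypes is not None:
        doc["phenotypes"] = {
            s: {"category": p.category.value, "folds": {str(k): v for k, v in p.folds.items()}}
            for s, p in phenotypes.items()
        }
    if params is not None:
        doc["params"] = params
    return doc


def report_text(doc: dict) -> str:
    """Human-readable companion to the JSON report."""
    call = doc["call"]
    lines = [
        f"Consensus BGC call: {call['first_gene']} .. {call['last_gene']} "
        f"({call['n_genes']} genes)",
        "",
        f"{'gene':<14} {'cg':<4} {'expression':<14} {'knockout':<12} tier",
    ]
    members = set(call["members"])
    for gene, e in doc.get("evidence", {}).items():
        member = gene in members
        if not (member or e["in_cg_span"] or e["reg_class"] or e["ko_category"]):
            continue  # plain background gene
        lines.append(
            f"{gene:<14} {'yes' if e['in_cg_span'] else '-':<4} "
            f"{e['reg_class'] or '-':<14} {e['ko_category'] or '-':<12} "
            f"{e['tier'] if member else 'excluded'}"
        )
    if doc.get("excluded"):
        lines.append("")
        lines.append("Excluded genes:")
        for x in doc["excluded"]:
            lines.append(f"  {x['gene']}: {x['reason']}")
    return "\n".join(lines) + "\n"


def write_report(doc: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(report_text(doc))
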
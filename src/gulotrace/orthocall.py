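"""Per-species presence/absence calls, lineage calls, and Dollo loss mapping.

Evidence from one genome (gene models, translated-search hits, contamination
screens) is distilled into a species-level call: PRESENT (an acceptable
HWAK-motif model), CONTAMINATION (the only motif-bearing models look
bacterial), INCONCLUSIVE (hits scattered over many scaffolds, or ambiguous
evidence), or ABSENT (no or only residual homology).  Lineage calls follow
the rule that absence is declared only when no ortholog with all expected
features is found in at least three species of the lineage.  Loss events
are mapped onto a species cladogram under Dollo parsimony: presence is the
ancestral state, a gene may be lost any number of times but never regained,
and each loss is pushed rootward to the deepest edge whose clade contains
no present tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy

from gulotrace.core_io import NucSeq, parse_newick, translate
from gulotrace.genemodel import GeneModel
from gulotrace.tsearch import HSP, SearchParams, karlin_stats
from Bio import Align

PRESENT = "PRESENT"
ABSENT = "ABSENT"
INCONCLUSIVE = "INCONCLUSIVE"
CONTAMINATION = "CONTAMINATION"

STATUS_COLOURS = {PRESENT: "green", ABSENT: "red",
                  INCONCLUSIVE: "blue", CONTAMINATION: "orange"}


@dataclass
class SpeciesCall:
    species: str
    status: str
    evidence: dict = field(default_factory=dict)


@dataclass
class LineageCall:
    lineage: str
    status: str
    species_calls: list[SpeciesCall] = field(default_factory=list)


@dataclass
class LossMap:
    tree: dendropy.Tree
    tip_states: dict[str, str]
    loss_clades: list[frozenset[str]]   # leaf sets below each loss edge

    @property
    def n_losses(self) -> int:
        return len(self.loss_clades)


# ---------------------------------------------------------------------------
# Contamination screening
# ---------------------------------------------------------------------------

_ALIGNER = Align.PairwiseAligner(mode="local", open_gap_score=-12,
                                 extend_gap_score=-1)
_ALIGNER.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")


def _best_bits(prot_a: str, prot_b: str) -> float:
    score = _ALIGNER.align(prot_a.replace("*", "X"), prot_b.replace("*", "X")).score
    bits, _ = karlin_stats(int(score), len(prot_a), len(prot_b), SearchParams())
    return bits


def screen_contamination(cds: NucSeq, reference_panel: dict[str, list[NucSeq]],
                         margin: float = 0.10) -> dict:
    """Compare a CDS against labelled animal and bacterial reference CDSs.

    The verdict is positive iff the best-scoring panel member (translated
    alignment, bit score) is bacterial and beats the best animal reference
    by at least ``margin`` (a fraction of the animal bit score).
    """
    animals = reference_panel.get("animal", [])
    bacteria = reference_panel.get("bacterial", [])
    if not animals or not bacteria:
        raise ValueError("panel must contain >=1 animal and >=1 bacterial reference")
    prot = translate(cds, 1).residues
    best_animal = max(_best_bits(prot, translate(r, 1).residues) for r in animals)
    best_bact = max(_best_bits(prot, translate(r, 1).residues) for r in bacteria)
    positive = best_bact > best_animal * (1 + margin)
    return {"positive": positive, "best_animal_bits": best_animal,
            "best_bacterial_bits": best_bact}


# ---------------------------------------------------------------------------
# Species and lineage calls
# ---------------------------------------------------------------------------

def _query_coverage(hsps: list[HSP], query_len: int) -> float:
    """Fraction of the query covered by the union of HSP query intervals."""
    if not hsps or query_len <= 0:
        return 0.0
    ivals = sorted((h.q_start, h.q_end) for h in hsps)
    covered, lo, hi = 0, *ivals[0]
    for s, e in ivals[1:]:
        if s <= hi:
            hi = max(hi, e)
        else:
            covered += hi - lo
            lo, hi = s, e
    covered += hi - lo
    return covered / query_len


def call_species(species: str, models: list[GeneModel], hsps: list[HSP],
                 query_len: int, scatter_min_scaffolds: int = 3,
                 residual_max: float = 0.25,
                 scatter_override_coverage: float = 0.9) -> SpeciesCall:
    """Distil one genome's evidence into a presence/absence call.

    Precedence: acceptable non-contaminated HWAK model -> PRESENT; only
    contaminated motif models -> CONTAMINATION; hits scattered over
    >= scatter_min_scaffolds scaffolds without a single-scaffold
    motif-bearing model -> INCONCLUSIVE; no or residual homology
    (query coverage < residual_max) -> ABSENT; otherwise INCONCLUSIVE.

    When hits are scattered across many scaffolds a partial single-scaffold
    model is not enough to declare presence: the model must carry all
    expected features, operationalised as query coverage >=
    ``scatter_override_coverage``.
    """
    coverage = _query_coverage(hsps, query_len)
    hit_scaffolds = sorted({h.scaffold_id for h in hsps})
    motif_models = [m for m in models if m.motif is not None]
    ev = {
        "n_hsps": len(hsps),
        "n_hit_scaffolds": len(hit_scaffolds),
        "hsp_query_coverage": round(coverage, 3),
        "n_models": len(models),
        "best_model": None,
    }
    scattered_evidence = len(hit_scaffolds) >= scatter_min_scaffolds
    good = [m for m in motif_models
            if m.acceptable and m.motif == "HWAK" and not m.contaminated
            and not (scattered_evidence
                     and m.coverage_frac < scatter_override_coverage)]
    if good:
        best = max(good, key=lambda m: m.score)
        ev["best_model"] = best
        ev["coverage_frac"] = best.coverage_frac
        return SpeciesCall(species, PRESENT, ev)
    if motif_models and all(m.contaminated for m in motif_models):
        ev["best_model"] = max(motif_models, key=lambda m: m.score)
        return SpeciesCall(species, CONTAMINATION, ev)
    single_scaffold_motif = [
        m for m in motif_models
        if len(set(m.scaffold_ids)) == 1 and not m.contaminated]
    if (len(hit_scaffolds) >= scatter_min_scaffolds
            and not any(m.acceptable for m in single_scaffold_motif)):
        ev["scattered"] = True
        return SpeciesCall(species, INCONCLUSIVE, ev)
    if not hsps or coverage < residual_max:
        return SpeciesCall(species, ABSENT, ev)
    return SpeciesCall(species, INCONCLUSIVE, ev)


def call_lineage(lineage: str, calls: list[SpeciesCall],
                 min_absent: int = 3) -> LineageCall:
    """PRESENT if any member species is PRESENT; ABSENT only when at least
    ``min_absent`` member species are ABSENT and none is PRESENT; otherwise
    INCONCLUSIVE (too few informative genomes to conclude)."""
    if not calls:
        raise ValueError("lineage call requires at least one species call")
    statuses = [c.status for c in calls]
    if PRESENT in statuses:
        return LineageCall(lineage, PRESENT, calls)
    if statuses.count(ABSENT) >= min_absent:
        return LineageCall(lineage, ABSENT, calls)
    return LineageCall(lineage, INCONCLUSIVE, calls)


# ---------------------------------------------------------------------------
# Dollo loss mapping
# ---------------------------------------------------------------------------

def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def dollo_losses(tree: dendropy.Tree | str, tip_states: dict[str, str]) -> LossMap:
    """Minimum independent loss events explaining tip presence/absence.

    The root state is fixed to present (the gene is ancestral); a loss on an
    edge makes every tip below it absent and no regain is allowed.  Unknown
    tips are unconstrained.  Each loss is placed canonically on the deepest
    (most rootward) edge whose clade contains no present tip.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown_tips = set(tip_states) - labels
    if unknown_tips:
        raise ValueError(f"tip states for labels not in tree: {sorted(unknown_tips)}")
    for lbl, st in tip_states.items():
        if st not in ("present", "absent", "unknown"):
            raise ValueError(f"invalid state {st!r} for {lbl!r}")

    def state(label: str) -> str:
        return tip_states.get(label, "unknown")

    losses: list[frozenset[str]] = []

    def visit(node, parent_has_present: bool):
        leaves = _leafset(node)
        has_present = any(state(l) == "present" for l in leaves)
        has_absent = any(state(l) == "absent" for l in leaves)
        if not has_present:
            if has_absent:
                losses.append(leaves)
            return
        for ch in node.child_nodes():
            visit(ch, True)

    # the root is constrained present, so its children are the deepest
    # edges a loss can sit on
    for ch in tree.seed_node.child_nodes():
        visit(ch, True)
    if not tree.seed_node.child_nodes():  # single-leaf degenerate tree
        leaves = _leafset(tree.seed_node)
        if any(state(l) == "absent" for l in leaves):
            losses.append(leaves)
    return LossMap(tree, dict(tip_states), losses)


def dollo_losses_bruteforce(tree: dendropy.Tree | str,
                            tip_states: dict[str, str]) -> int:
    """Exhaustive minimum over loss-edge subsets (oracle; small trees only)."""
    if isinstance(tree, str):
        tree = parse_newick(tree)
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    leafsets = [_leafset(n) for n in edges]
    present = {l for l, s in tip_states.items() if s == "present"}
    absent = {l for l, s in tip_states.items() if s == "absent"}
    for k in range(0, len(edges) + 1):
        for combo in combinations(range(len(edges)), k):
            lost = set().union(*(leafsets[i] for i in combo)) if combo else set()
            if absent <= lost and not (present & lost):
                return k
    raise RuntimeError("unreachable: losing every edge explains any pattern")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_callogram(tree: dendropy.Tree | str, calls: list[SpeciesCall]):
    """Cladogram annotated with call colours (green/red/blue/orange) plus a
    plain-text table.  Returns (figure, table_text)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(tree, str):
        tree = parse_newick(tree)
    if not calls:
        raise ValueError("no calls to render")
    by_species = {c.species: c for c in calls}
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in by_species]
    if missing:
        raise ValueError(f"calls missing for tips: {missing}")

    # leaf y positions, internal nodes midway between children
    ys: dict = {}
    for i, lf in enumerate(tree.leaf_node_iter()):
        ys[lf] = i
    depth = {tree.seed_node: 0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + 1
    max_d = max(depth.values()) or 1
    xs = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            xs[node] = max_d
        else:
            ys[node] = sum(ys[c] for c in node.child_nodes()) / len(node.child_nodes())
            xs[node] = depth[node]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(leaves) + 1))
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            ax.plot([xs[node], xs[node], xs[ch]],
                    [ys[node], ys[ch], ys[ch]], color="black", lw=1)
    for lf in tree.leaf_node_iter():
        call = by_species[lf.taxon.label]
        ax.text(xs[lf] + 0.05, ys[lf], f" {lf.taxon.label}",
                va="center", color=STATUS_COLOURS[call.status])
    ax.set_axis_off()

    rows = ["species\tstatus\tcolour"]
    rows += [f"{c.species}\t{c.status}\t{STATUS_COLOURS[c.status]}" for c in calls]
    return fig, "\n".join(rows) + "\n"


def lossmap_newick(lm: LossMap) -> str:
    """Annotated Newick: loss edges tagged with [&loss] comments."""
    tree = lm.tree.clone(depth=1)
    loss_sets = set(lm.loss_clades)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if _leafset(node) in loss_sets:
            lbl = node.taxon.label if node.is_leaf() else (node.label or "")
            if node.is_leaf():
                node.taxon.label = f"{lbl}[&loss]"
            else:
                node.label = "[&loss]"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# A Protostomia-style synthetic fixture: lineage cladogram and call states
# mirroring the published pattern of four independent losses (Pancrustacea,
# Nematoda, Platyhelminthes, Bivalvia) against a backdrop of lineages that
# retain the gene or lack enough genomes to decide.
# ---------------------------------------------------------------------------

PROTOSTOMIA_CLADOGRAM = (
    "((Priapulida,((Nematoda,Nematomorpha),((Tardigrada,Onychophora),"
    "((Araneae,Acari),Pancrustacea)))),"
    "((((Gastropoda,Bivalvia),Cephalopoda),(Annelida,Brachiopoda)),"
    "(Platyhelminthes,(Bryozoa,Rotifera))));"
)

PROTOSTOMIA_STATES = {
    "Priapulida": "present", "Araneae": "present", "Acari": "present",
    "Gastropoda": "present", "Annelida": "present", "Brachiopoda": "present",
    "Pancrustacea": "absent", "Nematoda": "absent",
    "Platyhelminthes": "absent", "Bivalvia": "absent",
    "Nematomorpha": "unknown", "Tardigrada": "unknown",
    "Onychophora": "unknown", "Cephalopoda": "unknown",
    "Bryozoa": "unknown", "Rotifera": "unknown",
}
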
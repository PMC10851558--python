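"""Synteny-ordered gene array across a set of reduced genomes.

Endosymbiont genome reduction proceeds almost exclusively by whole-gene
loss while conserving ancestral gene order, so homologous genes can be
arranged in an ordered array: one row per positional homolog family, one
column per genome.  Rows are anchored by reciprocal-best-hit assignments
to a shared reference proteome (or by identical gene names); unanchored
genes are interpolated between flanking anchors.  From the array follow
the pan/core genome, split-gene and duplication reports, strand
deviations and inversions, and syntenic blocks relative to the reference
gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GenomeRecord
from .homology import HomologAssignment, global_align, percent_identity


@dataclass
class ArrayRow:
    """One positional homolog family: per-genome gene lists with strands."""

    row_index: int
    ref_gene: str | None
    kind: str
    cells: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def present_in(self, genome_id: str) -> bool:
        return bool(self.cells.get(genome_id))

    @property
    def n_present(self) -> int:
        return sum(1 for v in self.cells.values() if v)


@dataclass
class GeneArray:
    rows: list[ArrayRow]
    genome_ids: list[str]

    def __len__(self) -> int:
        return len(self.rows)

    def reindex(self) -> None:
        for i, row in enumerate(self.rows):
            row.row_index = i

    def to_frame(self) -> pd.DataFrame:
        data = []
        for row in self.rows:
            rec = {
                "row_index": row.row_index,
                "ref_gene": row.ref_gene or "",
                "kind": row.kind,
                "flags": ";".join(sorted(row.flags)),
            }
            for gid in self.genome_ids:
                rec[gid] = ";".join(
                    f"{g}({s})" for g, s in row.cells.get(gid, [])
                )
            data.append(rec)
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SyntenicBlock:
    """Maximal run of array rows mapping to consecutive reference genes."""

    start_row: int
    end_row: int
    ref_start: int
    ref_end: int
    orientation: str  # 'same' or 'reversed'
    size: int


def _anchor_key(gene, assignment: HomologAssignment | None):
    if assignment is not None and assignment.reciprocal:
        return ("ref", assignment.ref_gene)
    if gene.name:
        return ("name", gene.name)
    return None


def _best_rotation(matched_positions: list[int | None], circular: bool) -> int:
    """Rotation of a gene order maximizing ascending runs of matched rows."""
    n = len(matched_positions)
    if not circular or n == 0:
        return 0

    def score(rot: int) -> int:
        seq = [
            matched_positions[(rot + i) % n]
            for i in range(n)
            if matched_positions[(rot + i) % n] is not None
        ]
        return sum(1 for a, b in zip(seq, seq[1:]) if b > a)

    best_rot, best_score = 0, -1
    for rot in range(n):
        s = score(rot)
        if s > best_score:
            best_rot, best_score = rot, s
    return best_rot


def build_array(
    genomes: list[GenomeRecord],
    assignments: dict[str, list[HomologAssignment]],
    proteomes: dict[str, dict[str, str]] | None = None,
    merge_identity: float = 30.0,
    duplication_rel_length: float = 70.0,
) -> GeneArray:
    """Assemble the cross-genome gene array.

    Rows are anchored on genes sharing a reciprocal reference assignment
    or an identical gene name.  Each circular gene order is rotated to
    maximize its agreement with the rows established so far.  Unanchored
    genes are placed between their flanking anchors, merging into an
    existing row only when their pairwise protein identity to a row
    member reaches ``merge_identity`` (requires ``proteomes``), otherwise
    opening a new row.  Rows whose per-genome strand disagrees with the
    row majority are flagged ``direction_change``.

    Raises ``ValueError`` if a genome shares no anchors with the rows
    built before it.
    """
    if len(genomes) == 0:
        raise ValueError("need at least one genome")
    amap: dict[str, dict[str, HomologAssignment]] = {
        gid: {a.query_gene: a for a in alist} for gid, alist in assignments.items()
    }
    rows: list[ArrayRow] = []
    key_rows: dict[tuple, list[ArrayRow]] = {}

    def new_row(at: int, key, gene, gid: str) -> ArrayRow:
        row = ArrayRow(row_index=-1, ref_gene=None, kind=gene.kind)
        row.cells[gid] = [(gene.gene_id, gene.strand)]
        rows.insert(at, row)
        if key is not None:
            key_rows.setdefault(key, []).append(row)
        return row

    # seed with the first genome's order
    first = genomes[0]
    for gene in first.genes:
        key = _anchor_key(gene, amap.get(first.genome_id, {}).get(gene.gene_id))
        new_row(len(rows), key, gene, first.genome_id)

    for genome in genomes[1:]:
        gid = genome.genome_id
        order = list(genome.genes)
        gmap = amap.get(gid, {})
        keys = [_anchor_key(g, gmap.get(g.gene_id)) for g in order]
        matched = [
            min(rows.index(r) for r in key_rows[k])
            if (k is not None and k in key_rows)
            else None
            for k in keys
        ]
        if all(m is None for m in matched):
            raise ValueError(
                f"no anchors between genomes {genomes[0].genome_id!r} and {gid!r}"
            )
        rot = _best_rotation(matched, genome.circular)
        order = order[rot:] + order[:rot]
        keys = keys[rot:] + keys[:rot]

        cursor = -1
        # genes without a matching row (unanchored, or anchored to a family
        # the earlier genomes lost) wait for their flanking anchor
        pending: list[tuple] = []

        def flush_pending(next_pos: int) -> None:
            nonlocal cursor
            for gene, key in pending:
                placed = False
                lo = max(cursor, 0)
                # the window includes the flanking anchor rows on both
                # sides: a split fragment may precede its anchored twin
                hi = min(next_pos + 1, len(rows))
                # merge only truly unanchored genes; a gene carrying its own
                # family key opens a row that later genomes can anchor to
                if key is None and proteomes is not None and gene.kind == "CDS":
                    qprot = proteomes.get(gid, {}).get(gene.gene_id)
                    if qprot:
                        best_row, best_ident = None, merge_identity
                        for row in rows[lo:hi]:
                            ident = _row_identity(row, gene.kind, qprot, proteomes)
                            if ident >= best_ident:
                                best_row, best_ident = row, ident
                        if best_row is not None:
                            best_row.cells.setdefault(gid, []).append(
                                (gene.gene_id, gene.strand)
                            )
                            cursor = rows.index(best_row)
                            placed = True
                if not placed:
                    at = cursor + 1
                    new_row(at, key, gene, gid)
                    cursor = at
            pending.clear()

        for gene, key in zip(order, keys):
            target = None
            if key is not None and key in key_rows:
                empties = [r for r in key_rows[key] if not r.present_in(gid)]
                if empties:
                    # nearest candidate just ahead of the cursor; fall back to
                    # the nearest anywhere (inversions run backwards)
                    target = min(
                        empties, key=lambda r: (abs(rows.index(r) - (cursor + 1)))
                    )
            if target is not None:
                tpos = rows.index(target)
                flush_pending(tpos)
                target.cells.setdefault(gid, []).append((gene.gene_id, gene.strand))
                cursor = rows.index(target)
            else:
                pending.append((gene, key))
        flush_pending(len(rows))

    if proteomes is not None:
        _refine_orphan_rows(rows, amap, proteomes, merge_identity)
    array = GeneArray(rows=rows, genome_ids=[g.genome_id for g in genomes])
    array.reindex()
    _assign_row_refs(array, amap)
    _flag_rows(array, amap, duplication_rel_length)
    return array


def _refine_orphan_rows(
    rows: list[ArrayRow],
    amap,
    proteomes: dict[str, dict[str, str]],
    merge_identity: float,
) -> None:
    """Fold single-occupant rows with no reference evidence into an
    adjacent row whose members they match by protein identity.

    Such rows arise when a severely deteriorated gene or split fragment
    in the row-seeding genome scores below the assignment floor; nearby
    high-identity neighbors are better evidence of its family than a row
    of its own.
    """
    i = 0
    while i < len(rows):
        row = rows[i]
        occupants = [
            (gid, entry) for gid, entries in row.cells.items() for entry in entries
        ]
        if len(occupants) != 1 or row.kind != "CDS":
            i += 1
            continue
        gid, (gene_id, strand) = occupants[0]
        a = amap.get(gid, {}).get(gene_id)
        if a is not None and a.ref_gene is not None:
            i += 1
            continue
        qprot = proteomes.get(gid, {}).get(gene_id)
        if not qprot:
            i += 1
            continue
        best, best_ident, best_prepend = None, merge_identity, False
        for j, prepend in ((i - 1, False), (i + 1, True)):
            if not (0 <= j < len(rows)):
                continue
            ident = _row_identity(rows[j], "CDS", qprot, proteomes)
            if ident >= best_ident:
                best, best_ident, best_prepend = rows[j], ident, prepend
        if best is not None:
            cell = best.cells.setdefault(gid, [])
            if best_prepend:
                cell.insert(0, (gene_id, strand))
            else:
                cell.append((gene_id, strand))
            del rows[i]
            i -= 1
        i += 1


def _row_identity(
    row: ArrayRow,
    kind: str,
    qprot: str,
    proteomes: dict[str, dict[str, str]],
) -> float:
    """Best pairwise protein identity of a gene against a row's members.

    Identity uses the shorter-sequence denominator so split fragments
    still look like their full-length row members.
    """
    if row.kind != kind:
        return -1.0
    best = -1.0
    for other_gid, entries in row.cells.items():
        for other_gene, _ in entries:
            other_prot = proteomes.get(other_gid, {}).get(other_gene)
            if not other_prot:
                continue
            aln = global_align(qprot, other_prot)
            best = max(best, percent_identity(aln, denominator="shorter"))
    return best


def _assign_row_refs(array: GeneArray, amap) -> None:
    """A row gets a reference identity if any member has a reciprocal match;
    failing that, the members' agreeing best (non-reciprocal) hit is used."""
    for row in array.rows:
        reciprocal_refs = []
        best_refs = []
        for gid, entries in row.cells.items():
            for gene_id, _ in entries:
                a = amap.get(gid, {}).get(gene_id)
                if a is None or a.ref_gene is None:
                    continue
                if a.reciprocal:
                    reciprocal_refs.append(a.ref_gene)
                best_refs.append(a.ref_gene)
        if reciprocal_refs:
            row.ref_gene = max(set(reciprocal_refs), key=reciprocal_refs.count)
        elif best_refs:
            row.ref_gene = max(set(best_refs), key=best_refs.count)


def _flag_rows(array: GeneArray, amap, duplication_rel_length: float) -> None:
    for row in array.rows:
        for gid, entries in row.cells.items():
            if len(entries) > 1:
                rels = [
                    amap.get(gid, {}).get(g).relative_length
                    if amap.get(gid, {}).get(g) is not None
                    else 0.0
                    for g, _ in entries
                ]
                if all(r >= duplication_rel_length for r in rels):
                    row.flags.add("duplicated")
                else:
                    row.flags.add("split")
        strands = [v[0][1] for v in row.cells.values() if v]
        if len(set(strands)) > 1:
            row.flags.add("direction_change")


def pan_core(array: GeneArray) -> dict:
    """Pan and core gene counts per kind after compacting duplicated rows.

    Rows sharing the same reference identity are compacted into one pan
    unit; a unit is core when, across its compacted rows, every genome
    has at least one gene.
    """
    units: dict[object, list[ArrayRow]] = {}
    for row in array.rows:
        key = ("ref", row.ref_gene) if row.ref_gene else ("row", row.row_index)
        units.setdefault(key, []).append(row)
    pan_by_kind: dict[str, int] = {}
    core_by_kind: dict[str, int] = {}
    for key, unit_rows in units.items():
        kind = unit_rows[0].kind
        pan_by_kind[kind] = pan_by_kind.get(kind, 0) + 1
        present = {
            gid
            for row in unit_rows
            for gid, entries in row.cells.items()
            if entries
        }
        if present == set(array.genome_ids):
            core_by_kind[kind] = core_by_kind.get(kind, 0) + 1
    return {
        "pan_by_kind": pan_by_kind,
        "core_by_kind": core_by_kind,
        "pan_total": sum(pan_by_kind.values()),
        "core_total": sum(core_by_kind.values()),
    }


def detect_splits(
    array: GeneArray,
    assignments: dict[str, list[HomologAssignment]],
    genomes: list[GenomeRecord],
    length_tolerance: float = 0.15,
    internal_stop_genes: dict[str, list[str]] | None = None,
    max_intervening: int = 1,
) -> pd.DataFrame:
    """Report genes split into fragments.

    A split is two or more genes adjacent in one genome's order (up to
    ``max_intervening`` intervening genes allowed) whose best reference
    hit is the same gene and whose summed amino-acid length falls within
    ``1 +/- length_tolerance`` of the reference length.  A gene without
    its own reference hit (fragments often score below the RBH threshold)
    inherits the reference identity of its array row; its relative length
    is then prorated from the lengths of its co-fragments.  Genes
    translated with an internal stop codon are additionally reported as
    candidates.  Two adjacent full-length copies fail the summed-length
    test and are classified as a duplication instead.
    """
    amap = {gid: {a.query_gene: a for a in al} for gid, al in assignments.items()}
    row_ref: dict[tuple[str, str], str] = {}
    for row in array.rows:
        if row.ref_gene:
            for gid, entries in row.cells.items():
                for gene_id, _ in entries:
                    row_ref[(gid, gene_id)] = row.ref_gene

    def effective_ref(gid: str, gene_id: str) -> str | None:
        a = amap.get(gid, {}).get(gene_id)
        if a is not None and a.ref_gene is not None:
            return a.ref_gene
        return row_ref.get((gid, gene_id))

    records = []
    for genome in genomes:
        gid = genome.genome_id
        gmap = amap.get(gid, {})
        order = list(genome.genes)
        n = len(order)
        i = 0
        used: set[str] = set()
        while i < n:
            ref_i = effective_ref(gid, order[i].gene_id)
            if ref_i is None or order[i].gene_id in used:
                i += 1
                continue
            group = [order[i]]
            j = i + 1
            gap = 0
            while j < n and gap <= max_intervening:
                if effective_ref(gid, order[j].gene_id) == ref_i:
                    group.append(order[j])
                    gap = 0
                else:
                    gap += 1
                j += 1
            rels = []
            with_rel = [
                (g, gmap[g.gene_id].relative_length)
                for g in group
                if g.gene_id in gmap
                and gmap[g.gene_id].ref_gene == ref_i
                and gmap[g.gene_id].relative_length > 0
            ]
            # amino-acid length per percent of the reference, from the
            # fragments that do carry a direct assignment
            aa_per_pct = (
                sum(g.length / 3.0 - 1.0 for g, _ in with_rel)
                / sum(r for _, r in with_rel)
                if with_rel
                else None
            )
            for g in group:
                a = gmap.get(g.gene_id)
                if a is not None and a.ref_gene == ref_i and a.relative_length > 0:
                    rels.append(a.relative_length)
                elif aa_per_pct:
                    rels.append((g.length / 3.0 - 1.0) / aa_per_pct)
                else:
                    rels.append(0.0)
            if len(group) >= 2:
                total_rel = sum(rels) / 100.0
                if 1.0 - length_tolerance <= total_rel <= 1.0 + length_tolerance:
                    records.append(
                        {
                            "genome_id": gid,
                            "ref_gene": ref_i,
                            "fragments": ";".join(g.gene_id for g in group),
                            "n_fragments": len(group),
                            "summed_relative_length": 100.0 * total_rel,
                            "evidence": "adjacent_same_ref",
                        }
                    )
                    used.update(g.gene_id for g in group)
            i += 1
        for gene_id in (internal_stop_genes or {}).get(gid, []):
            if gene_id not in used:
                a = gmap.get(gene_id)
                records.append(
                    {
                        "genome_id": gid,
                        "ref_gene": a.ref_gene if a else "",
                        "fragments": gene_id,
                        "n_fragments": 1,
                        "summed_relative_length": a.relative_length if a else float("nan"),
                        "evidence": "internal_stop",
                    }
                )
    return pd.DataFrame(
        records,
        columns=[
            "genome_id", "ref_gene", "fragments", "n_fragments",
            "summed_relative_length", "evidence",
        ],
    )


def _genome_order_index(genome: GenomeRecord) -> dict[str, int]:
    return {g.gene_id: i for i, g in enumerate(genome.genes)}


def strand_deviations(
    array: GeneArray,
    genomes: list[GenomeRecord] | None = None,
    ref_strands: dict[str, str] | None = None,
) -> dict:
    """Classify strand disagreements into isolated direction changes and
    inversions.

    An inversion is a maximal run of two or more consecutive rows where
    one genome's strand is flipped relative to the row majority *and*
    (when genome records are supplied) its local gene order runs
    backwards; isolated flips — or runs without order reversal — are
    direction changes.  ``ref_strands`` (reference gene id -> strand),
    when given, replaces the within-row majority as the orientation
    baseline — two-genome majorities are unresolvable and overlapping
    inversions can invert the majority itself.
    """
    order_idx = (
        {g.genome_id: _genome_order_index(g) for g in genomes} if genomes else None
    )
    flips: dict[str, list[int]] = {gid: [] for gid in array.genome_ids}
    for row in array.rows:
        strands = [v[0][1] for v in row.cells.values() if v]
        if not strands:
            continue
        if ref_strands and row.ref_gene in ref_strands:
            # the reference orientation is the baseline when available;
            # overlapping inversions can flip the within-row majority
            majority = ref_strands[row.ref_gene]
        else:
            majority = max(set(strands), key=strands.count)
            if strands.count(majority) * 2 == len(strands):
                majority = "+"  # even split with no reference: fixed rule
        for gid in array.genome_ids:
            entries = row.cells.get(gid) or []
            if entries and entries[0][1] != majority:
                flips[gid].append(row.row_index)

    direction_changes: list[dict] = []
    inversions: list[dict] = []
    for gid, row_ids in flips.items():
        runs: list[list[int]] = []
        for r in sorted(row_ids):
            if runs and _next_present_row(array, gid, runs[-1][-1]) == r:
                runs[-1].append(r)
            else:
                runs.append([r])
        for run in runs:
            genes = [array.rows[r].cells[gid][0][0] for r in run]
            reversed_order = False
            if order_idx is not None and len(run) >= 2:
                idx = [order_idx[gid].get(g) for g in genes]
                if None not in idx:
                    reversed_order = all(b < a for a, b in zip(idx, idx[1:]))
            if len(run) >= 2 and (order_idx is None or reversed_order):
                inversions.append(
                    {
                        "genome_id": gid,
                        "start_row": run[0],
                        "end_row": run[-1],
                        "size": len(run),
                        "genes": genes,
                    }
                )
            else:
                for r, g in zip(run, genes):
                    direction_changes.append(
                        {"genome_id": gid, "row_index": r, "gene_id": g}
                    )
    return {"direction_changes": direction_changes, "inversions": inversions}


def _next_present_row(array: GeneArray, gid: str, after: int) -> int | None:
    for row in array.rows[after + 1 :]:
        if row.present_in(gid):
            return row.row_index
    return None


def syntenic_blocks(
    array: GeneArray,
    ref_order: list[str],
    skip_unassigned: bool = True,
) -> list[SyntenicBlock]:
    """Maximal runs of rows mapping to consecutive reference genes.

    Rows are scanned in array order; a block extends while successive
    reference indices step by +1 (orientation ``same``) or -1
    (``reversed``).  Rows without a reference assignment are skipped
    without breaking the block when ``skip_unassigned`` (severely
    deteriorated genes would otherwise shatter blocks); ``size`` counts
    the reference-assigned rows in the block.
    """
    ref_index = {g: i for i, g in enumerate(ref_order)}
    assigned = [
        (row.row_index, ref_index[row.ref_gene])
        for row in array.rows
        if row.ref_gene in ref_index
    ]
    if not assigned:
        raise ValueError("no rows carry a reference assignment")
    if not skip_unassigned:
        # break blocks at unassigned rows by splitting the scan there
        segments: list[list[tuple[int, int]]] = []
        seg: list[tuple[int, int]] = []
        for row in array.rows:
            if row.ref_gene in ref_index:
                seg.append((row.row_index, ref_index[row.ref_gene]))
            elif seg:
                segments.append(seg)
                seg = []
        if seg:
            segments.append(seg)
    else:
        segments = [assigned]

    blocks: list[SyntenicBlock] = []
    for seg in segments:
        cur = [seg[0]]
        direction = 0
        for prev, nxt in zip(seg, seg[1:]):
            step = nxt[1] - prev[1]
            if step in (1, -1) and (direction == 0 or step == direction):
                cur.append(nxt)
                direction = step
            else:
                blocks.append(_close_block(cur, direction))
                cur, direction = [nxt], 0
        blocks.append(_close_block(cur, direction))
    return blocks


def _close_block(cur: list[tuple[int, int]], direction: int) -> SyntenicBlock:
    refs = [c[1] for c in cur]
    return SyntenicBlock(
        start_row=cur[0][0],
        end_row=cur[-1][0],
        ref_start=min(refs),
        ref_end=max(refs),
        orientation="reversed" if direction == -1 else "same",
        size=len(cur),
    )


def blocks_frame(blocks: list[SyntenicBlock]) -> pd.DataFrame:
    return pd.DataFrame([b.__dict__ for b in blocks])


def presence_matrix(array: GeneArray) -> pd.DataFrame:
    """Binary gene presence/absence matrix (rows x genomes)."""
    data = {
        gid: [1 if row.present_in(gid) else 0 for row in array.rows]
        for gid in array.genome_ids
    }
    return pd.DataFrame(data, index=[row.row_index for row in array.rows])


def order_violations(array: GeneArray, genome: GenomeRecord) -> int:
    """Count adjacent cell pairs read top-to-bottom that are out of genomic
    order for ``genome`` (one circular rotation allowed)."""
    idx = _genome_order_index(genome)
    seq = [
        idx[g]
        for row in array.rows
        for g, _ in row.cells.get(genome.genome_id, [])
        if g in idx
    ]
    if len(seq) < 2:
        return 0
    breaks = sum(1 for a, b in zip(seq, seq[1:]) if b <= a)
    # a single wrap of the circular origin is not a violation
    return max(0, breaks - (1 if genome.circular else 0))
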
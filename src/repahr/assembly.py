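"""Contig assembly of the high-frequency reads and the repeat-library filters.

The built-in assembler is a deliberately minimal de Bruijn unitig assembler:
canonical k_asm-mers are edges with multiplicities, low-multiplicity edges are
pruned, and maximal unbranched paths are emitted as contigs.  It exists so the
pipeline is verifiable end to end without external tools; an adapter hook
(:func:`run_external_assembler`) lets a production run substitute a real
assembler such as SPAdes.  Contigs are then filtered by mean k-mer coverage
and length into the final repeat library.
"""

from __future__ import annotations

import logging
import re
import shlex
import subprocess
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from .kmer import decode_kmer, revcomp, revcomp_code
from .seqio import SeqRecord, read_sequences, write_fasta
from .spectrum import count_kmers

logger = logging.getLogger(__name__)

_COV_RE = re.compile(r"cov[_=]([0-9]+(?:\.[0-9]+)?)")


@dataclass
class DeBruijnGraph:
    """Edges are canonical k_asm-mers with multiplicity; nodes (k_asm-1)-mers."""

    k_asm: int
    edges: dict[int, int]
    nodes: set[int]
    prune_below: int = 1


@dataclass
class RepeatContig:
    contig_id: str
    seq: str
    length: int
    mean_cov: float
    n_edges: int = 0


def build_graph(reads, k_asm: int, prune_below: int = 2) -> DeBruijnGraph:
    """Count canonical assembly k-mers and prune low-multiplicity edges.

    k_asm must be odd (no palindromic k-mer is then its own reverse
    complement).  Raises ``ValueError`` when no read reaches k_asm.
    """
    if k_asm % 2 == 0:
        raise ValueError(f"k_asm must be odd, got {k_asm}")
    try:
        table = count_kmers(reads, k_asm, canonical=True)
    except ValueError as exc:
        raise ValueError("no assembly k-mers") from exc
    if not table.code_counts:
        raise ValueError("no assembly k-mers")
    edges = {c: n for c, n in table.code_counts.items() if n >= prune_below}
    mask1 = (1 << (2 * (k_asm - 1))) - 1
    nodes: set[int] = set()
    for e in edges:
        r = revcomp_code(e, k_asm)
        for x in (e, r):
            nodes.add(min(x >> 2, revcomp_code(x >> 2, k_asm - 1)))
            nodes.add(min(x & mask1, revcomp_code(x & mask1, k_asm - 1)))
    return DeBruijnGraph(k_asm=k_asm, edges=edges, nodes=nodes, prune_below=prune_below)


def emit_contigs(graph: DeBruijnGraph) -> list[RepeatContig]:
    """Emit maximal unbranched paths (unitigs) as contigs.

    Each unitig is reported once, in canonical orientation (lexicographically
    smaller of the sequence and its reverse complement), sorted by descending
    length then sequence.  ``mean_cov`` is the mean edge multiplicity along
    the path.
    """
    k = graph.k_asm
    mask1 = (1 << (2 * (k - 1))) - 1
    adj: dict[int, list] = defaultdict(list)
    indeg: dict[int, int] = defaultdict(int)
    for e in graph.edges:
        r = revcomp_code(e, k)
        for x in (e, r):
            u, v = x >> 2, x & mask1
            adj[u].append((v, x & 3, e))
            indeg[v] += 1
    for lst in adj.values():
        lst.sort()

    visited: set[int] = set()
    bases = "ACGT"
    results: list[tuple[str, float, int]] = []

    def is_through(node: int) -> bool:
        return indeg.get(node, 0) == 1 and len(adj.get(node, ())) == 1

    def walk(u: int, v: int, last: int, e: int):
        visited.add(e)
        seq = [decode_kmer(u, k - 1), bases[last]]
        covs = [graph.edges[e]]
        cur = v
        while is_through(cur):
            nv, nb, ne = adj[cur][0]
            if ne in visited:
                break
            visited.add(ne)
            seq.append(bases[nb])
            covs.append(graph.edges[ne])
            cur = nv
        s = "".join(seq)
        rc = revcomp(s)
        results.append((min(s, rc), sum(covs) / len(covs), len(covs)))

    starts = sorted(u for u in adj if not is_through(u))
    for u in starts:
        for v, last, e in adj[u]:
            if e not in visited:
                walk(u, v, last, e)
    # leftover edges sit on isolated cycles
    for u in sorted(adj):
        for v, last, e in adj[u]:
            if e not in visited:
                walk(u, v, last, e)

    results.sort(key=lambda r: (-len(r[0]), r[0]))
    return [
        RepeatContig(
            contig_id=f"repahr_contig_{i}",
            seq=s,
            length=len(s),
            mean_cov=cov,
            n_edges=n,
        )
        for i, (s, cov, n) in enumerate(results, 1)
    ]


def assemble_reads(reads, k_asm: int = 31, prune_below: int = 2) -> list[RepeatContig]:
    """Convenience wrapper: graph construction followed by unitig emission."""
    return emit_contigs(build_graph(reads, k_asm, prune_below))


def filter_contigs(contigs, min_cov: float, min_len: int) -> list[RepeatContig]:
    """Keep contigs with mean_cov >= min_cov and length >= min_len.

    Survivors are sorted by descending length (ties by sequence) and
    renumbered.
    """
    kept = [c for c in contigs if c.mean_cov >= min_cov and c.length >= min_len]
    kept.sort(key=lambda c: (-c.length, c.seq))
    if contigs and not kept:
        logger.warning("all %d contigs removed by the coverage/length filters", len(contigs))
    return [
        RepeatContig(f"repahr_contig_{i}", c.seq, c.length, c.mean_cov, c.n_edges)
        for i, c in enumerate(kept, 1)
    ]


def run_external_assembler(
    read_paths,
    adapter_cmd: str,
    workdir,
    k_asm: int = 31,
) -> list[RepeatContig]:
    """Invoke an external assembler through a command template.

    The template receives ``{reads}`` (space-joined input paths), ``{output}``
    (the contig FASTA the command must create) and ``{workdir}``.  Contig
    coverage is parsed from a ``cov_<float>`` token in headers when present,
    otherwise recomputed by mapping k-mer counts of the input reads onto each
    contig.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out_fasta = workdir / "external_contigs.fasta"
    cmd = adapter_cmd.format(
        reads=" ".join(shlex.quote(str(p)) for p in read_paths),
        output=shlex.quote(str(out_fasta)),
        workdir=shlex.quote(str(workdir)),
    )
    logger.info("running external assembler: %s", cmd)
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode == 127:
        raise RuntimeError(f"assembler not found: {cmd}")
    if proc.returncode != 0:
        tail = (proc.stderr or proc.stdout or "")[-2000:]
        raise RuntimeError(f"assembler exited with {proc.returncode}:\n{tail}")
    if not out_fasta.exists():
        raise RuntimeError(f"assembler produced no output at {out_fasta}")

    records = list(read_sequences(out_fasta))
    if not records:
        raise RuntimeError("assembler output FASTA holds no contigs")

    need_remap = any(_COV_RE.search(r.header) is None for r in records)
    table = None
    if need_remap:
        read_recs = []
        for p in read_paths:
            read_recs.extend(read_sequences(p))
        table = count_kmers(read_recs, k_asm, canonical=True)

    contigs = []
    for i, rec in enumerate(records, 1):
        m = _COV_RE.search(rec.header)
        if m:
            cov = float(m.group(1))
        else:
            cov = _remap_coverage(rec.seq, table)
        contigs.append(
            RepeatContig(f"repahr_contig_{i}", rec.seq, len(rec.seq), cov)
        )
    contigs.sort(key=lambda c: (-c.length, c.seq))
    return [
        RepeatContig(f"repahr_contig_{i}", c.seq, c.length, c.mean_cov, c.n_edges)
        for i, c in enumerate(contigs, 1)
    ]


def _remap_coverage(seq: str, table) -> float:
    from .kmer import window_codes

    vals, valid = window_codes(seq, table.k, canonical=True)
    if not valid.any():
        return 0.0
    counts = [table.code_counts.get(v, 0) for v, ok in zip(vals.tolist(), valid.tolist()) if ok]
    return sum(counts) / len(counts)


def write_repeat_library(contigs, path, wrap: int = 80) -> int:
    """Write the final library: ``>repahr_contig_<n> length=<L> cov=<mean_cov>``."""
    records = [
        SeqRecord(id=c.contig_id, seq=c.seq, desc=f"length={c.length} cov={c.mean_cov:.2f}")
        for c in contigs
    ]
    return write_fasta(records, path, wrap=wrap)
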
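"""Readers and writers for the cluster annotation dialect.

Two on-disk representations are supported and round-trip losslessly:

* **GenBank** — one record per cluster; the record sequence is the
  concatenation of the gene sequences in order. Each gene is a ``CDS``
  feature (``/locus_tag``), each module a ``misc_feature`` with
  ``/note="module:<index>"``, and each domain a ``misc_feature`` with
  ``/note="domain:<KIND>;active:<true|false>;substrate:<malonyl|methylmalonyl|->"``.
  Absence of the activity flag defaults to active. GenBank files use
  the format's 1-based inclusive coordinates; Biopython converts to
  the internal 0-based half-open convention on the way in and out.
  Reverse-strand CDS are reverse-complemented at parse time so the
  in-memory model is always forward-strand.

* **JSON** — a direct, schema-stable mirror of the dataclasses
  (sorted keys, so writers are deterministic).

FASTA writers emit fixed 60-column lines.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import ClusterParseError
from .model import (
    DomainAnnotation,
    Gene,
    HybridRecord,
    ModuleDef,
    PKSCluster,
    translate_gene,
)

__all__ = [
    "load_cluster",
    "write_cluster",
    "cluster_to_dict",
    "cluster_from_dict",
    "write_fasta",
    "read_fasta",
    "write_hybrid_fasta",
]

_SUBSTRATE_OUT = {"malonyl": "malonyl", "methylmalonyl": "methylmalonyl", "none": "-"}
_SUBSTRATE_IN = {v: k for k, v in _SUBSTRATE_OUT.items()}


# --- JSON schema ------------------------------------------------------


def cluster_to_dict(cluster: PKSCluster) -> dict:
    return {
        "name": cluster.name,
        "loading_present": cluster.loading_present,
        "genes": [
            {"gene_id": g.gene_id, "nt_seq": g.nt_seq, "strand": g.strand}
            for g in cluster.genes
        ],
        "modules": [
            {
                "index": m.index,
                "gene_id": m.gene_id,
                "aa_seq": m.aa_seq,
                "nt_interval": list(m.nt_interval),
                "domains": [
                    {
                        "kind": d.kind,
                        "aa_interval": list(d.aa_interval),
                        "active": d.active,
                        "at_substrate": d.at_substrate,
                    }
                    for d in m.domains
                ],
            }
            for m in cluster.modules
        ],
    }


def cluster_from_dict(data: dict) -> PKSCluster:
    genes = [Gene(g["gene_id"], g["nt_seq"], g.get("strand", "+")) for g in data["genes"]]
    modules = [
        ModuleDef(
            index=m["index"],
            gene_id=m["gene_id"],
            aa_seq=m["aa_seq"],
            nt_interval=tuple(m["nt_interval"]),
            domains=[
                DomainAnnotation(
                    kind=d["kind"],
                    aa_interval=tuple(d["aa_interval"]),
                    active=d.get("active", True),
                    at_substrate=d.get("at_substrate", "none"),
                )
                for d in m["domains"]
            ],
        )
        for m in data["modules"]
    ]
    return PKSCluster(
        name=data["name"],
        genes=genes,
        modules=modules,
        loading_present=data.get("loading_present", 0 in {m.index for m in modules}),
    )


# --- GenBank ----------------------------------------------------------


def _cluster_to_record(cluster: PKSCluster) -> SeqRecord:
    record = SeqRecord(
        Seq(cluster.genome()),
        id=cluster.name[:16] or "cluster",
        name=cluster.name[:16] or "cluster",
        description=f"PKS cluster {cluster.name}",
        annotations={"molecule_type": "DNA"},
    )
    for gene in cluster.genes:
        off = cluster.gene_offset(gene.gene_id)
        record.features.append(
            SeqFeature(
                SimpleLocation(off, off + len(gene.nt_seq), strand=1),
                type="CDS",
                qualifiers={"locus_tag": [gene.gene_id]},
            )
        )
    for m in cluster.modules:
        ms, me = cluster.module_genome_interval(m)
        record.features.append(
            SeqFeature(
                SimpleLocation(ms, me, strand=1),
                type="misc_feature",
                qualifiers={"note": [f"module:{m.index}"]},
            )
        )
        for d in m.domains:
            ds = ms + 3 * d.aa_interval[0]
            de = ms + 3 * d.aa_interval[1]
            note = (
                f"domain:{d.kind};active:{'true' if d.active else 'false'};"
                f"substrate:{_SUBSTRATE_OUT[d.at_substrate]}"
            )
            record.features.append(
                SeqFeature(
                    SimpleLocation(ds, de, strand=1),
                    type="misc_feature",
                    qualifiers={"note": [note]},
                )
            )
    return record


def _parse_domain_note(note: str) -> dict | None:
    if not note.startswith("domain:"):
        return None
    fields = dict(
        part.split(":", 1) for part in note.split(";") if ":" in part
    )
    kind = fields["domain"]
    active = fields.get("active", "true").lower() != "false"
    substrate = _SUBSTRATE_IN.get(fields.get("substrate", "-"), "none")
    return {"kind": kind, "active": active, "at_substrate": substrate}


def _record_to_cluster(record: SeqRecord, name: str | None = None) -> PKSCluster:
    full = str(record.seq).upper()
    cds_feats = [f for f in record.features if f.type == "CDS"]
    if not cds_feats:
        raise ClusterParseError("no CDS features in record")
    cds_feats.sort(key=lambda f: int(f.location.start))

    genes: list[Gene] = []
    gene_spans: list[tuple[int, int, str, int]] = []  # start, end, id, strand
    for i, feat in enumerate(cds_feats):
        gid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [f"gene{i + 1}"]))[0]
        s, e = int(feat.location.start), int(feat.location.end)
        strand = feat.location.strand or 1
        seq = full[s:e]
        if strand == -1:
            seq = str(Seq(seq).reverse_complement())
        genes.append(Gene(gid, seq, "+" if strand == 1 else "-"))
        gene_spans.append((s, e, gid, strand))

    def locate_gene(s: int, e: int, what: str) -> tuple[str, int, int, int]:
        """Map genomic [s, e) into gene-local forward-strand coordinates."""
        for gs, ge, gid, strand in gene_spans:
            if gs <= s and e <= ge:
                if strand == 1:
                    return gid, s - gs, e - gs, strand
                return gid, ge - e, ge - s, strand
        raise ClusterParseError(f"{what} at [{s}, {e}) not inside any CDS", feature=what)

    modules: list[ModuleDef] = []
    module_feats = []
    domain_feats = []
    for feat in record.features:
        if feat.type != "misc_feature":
            continue
        note = feat.qualifiers.get("note", [""])[0]
        if note.startswith("module:"):
            module_feats.append((int(note.split(":", 1)[1]), feat))
        else:
            parsed = _parse_domain_note(note)
            if parsed is not None:
                domain_feats.append((parsed, feat))

    for index, feat in module_feats:
        s, e = int(feat.location.start), int(feat.location.end)
        gid, ls, le, _ = locate_gene(s, e, f"module:{index}")
        gene = next(g for g in genes if g.gene_id == gid)
        aa = translate_gene(gene.nt_seq[ls:le])
        domains = []
        for parsed, dfeat in domain_feats:
            ds, de = int(dfeat.location.start), int(dfeat.location.end)
            if not (s <= ds and de <= e):
                continue
            dgid, dls, dle, _ = locate_gene(ds, de, f"domain:{parsed['kind']}")
            if dgid != gid:
                raise ClusterParseError(
                    "domain crosses gene boundary", feature=f"domain:{parsed['kind']}"
                )
            domains.append(
                DomainAnnotation(
                    kind=parsed["kind"],
                    aa_interval=((dls - ls) // 3, (dle - ls) // 3),
                    active=parsed["active"],
                    at_substrate=parsed["at_substrate"],
                )
            )
        domains.sort(key=lambda d: d.aa_interval[0])
        for a, b in zip(domains, domains[1:]):
            if b.aa_interval[0] < a.aa_interval[1]:
                raise ClusterParseError(
                    f"overlapping domains {a.kind}/{b.kind} in module {index}",
                    feature=f"module:{index}",
                )
        modules.append(
            ModuleDef(index=index, gene_id=gid, aa_seq=aa, nt_interval=(ls, le), domains=domains)
        )

    modules.sort(key=lambda m: m.index)
    return PKSCluster(
        name=name or record.id,
        genes=genes,
        modules=modules,
        loading_present=any(m.index == 0 for m in modules),
    )


# --- public entry points ----------------------------------------------


def load_cluster(path: str | Path) -> PKSCluster:
    """Load a cluster from an annotated GenBank file (``.gb``/``.gbk``)
    or the JSON cluster schema (``.json``)."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return cluster_from_dict(json.load(fh))
    record = SeqIO.read(str(path), "genbank")
    return _record_to_cluster(record, name=path.stem)


def write_cluster(cluster: PKSCluster, path: str | Path) -> Path:
    """Write a cluster as GenBank or JSON depending on the suffix.
    Writers are deterministic (sorted JSON keys, fixed feature order)."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(cluster_to_dict(cluster), fh, sort_keys=True, indent=2)
            fh.write("\n")
    else:
        SeqIO.write([_cluster_to_record(cluster)], str(path), "genbank")
    return path


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    """Write (id, sequence) pairs as FASTA with 60-column lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_hybrid_fasta(hybrids: list[HybridRecord], path: str | Path, kind: str = "nt") -> Path:
    attr = "nt_seq" if kind == "nt" else "aa_seq"
    return write_fasta([(h.seq_id, getattr(h, attr)) for h in hybrids], path)
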
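"""Run configuration, FASTA/snapshot readers and writers, run logging.

The run configuration is a YAML file with sections ``params`` (every rate
constant and system size), ``run`` (cycles, seed, output), ``wordgraph``,
``circle`` and ``protocell``.  Unknown keys are rejected and a configuration
round-trips losslessly through its file form; an empty file yields the
standard parameter set.

A mixture snapshot is a FASTA file of strands (id, cycle and per-cycle
bookkeeping in the description) plus a sidecar tab-separated table of
helices (strand ids, 0-based starts, length) with monomer counts in
comment lines; reading a snapshot reproduces strands, helices, clusters
and monomer counts exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circlefinder import AnnealSchedule
from .core import (BASES, Cluster, InconsistentStateError, Mixture,
                   Parameters, Strand)

log = logging.getLogger("vcgsim")


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass
class RunConfig:
    """Complete description of one run; defaults are the standard values."""

    params: Parameters = field(default_factory=Parameters)
    n_cycles: int = 500
    seed: int = 0
    outdir: str = "out"
    snapshot_every: int = 0          # 0 = no snapshots
    # word statistics
    word_k: int = 5
    n_cap: int = 30
    # circle search
    circle_L: int = 114
    circle_w: int = 4
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    # protocells
    n_cells: int = 50
    mode: str = "none"
    protocell_cycles: int = 200

    def to_dict(self) -> Dict[str, dict]:
        params = dataclasses.asdict(self.params)
        params["r_ex"] = [list(row) for row in self.params.r_ex]
        return {
            "params": params,
            "run": {"n_cycles": self.n_cycles, "seed": self.seed,
                    "outdir": self.outdir,
                    "snapshot_every": self.snapshot_every},
            "wordgraph": {"k": self.word_k, "n_cap": self.n_cap},
            "circle": {"L": self.circle_L, "w": self.circle_w,
                       **dataclasses.asdict(self.schedule)},
            "protocell": {"n_cells": self.n_cells, "mode": self.mode,
                          "cycles": self.protocell_cycles},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_RUN_KEYS = {"n_cycles", "seed", "outdir", "snapshot_every"}
_WG_KEYS = {"k", "n_cap"}
_CIRCLE_KEYS = {"L", "w"} | {f.name for f in dataclasses.fields(AnnealSchedule)}
_CELL_KEYS = {"n_cells", "mode", "cycles"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(Parameters)}


def config_from_dict(data: Optional[dict]) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - {"params", "run", "wordgraph", "circle", "protocell"}
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    cfg = RunConfig()

    pdata = dict(data.get("params") or {})
    bad = set(pdata) - _PARAM_KEYS
    if bad:
        raise ConfigError(f"unknown parameter keys: {sorted(bad)}")
    if "r_ex" in pdata:
        pdata["r_ex"] = tuple(tuple(row) for row in pdata["r_ex"])
    try:
        cfg.params = Parameters(**pdata)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid parameter value: {exc}") from exc

    rdata = dict(data.get("run") or {})
    bad = set(rdata) - _RUN_KEYS
    if bad:
        raise ConfigError(f"unknown run keys: {sorted(bad)}")
    for key, val in rdata.items():
        setattr(cfg, key, val)
    if cfg.n_cycles < 0 or cfg.snapshot_every < 0:
        raise ConfigError("cycle counts must be non-negative")

    wdata = dict(data.get("wordgraph") or {})
    bad = set(wdata) - _WG_KEYS
    if bad:
        raise ConfigError(f"unknown wordgraph keys: {sorted(bad)}")
    cfg.word_k = wdata.get("k", cfg.word_k)
    cfg.n_cap = wdata.get("n_cap", cfg.n_cap)

    cdata = dict(data.get("circle") or {})
    bad = set(cdata) - _CIRCLE_KEYS
    if bad:
        raise ConfigError(f"unknown circle keys: {sorted(bad)}")
    cfg.circle_L = cdata.pop("L", cfg.circle_L)
    cfg.circle_w = cdata.pop("w", cfg.circle_w)
    try:
        cfg.schedule = AnnealSchedule(**cdata) if cdata else AnnealSchedule()
    except ValueError as exc:
        raise ConfigError(f"invalid schedule value: {exc}") from exc

    celldata = dict(data.get("protocell") or {})
    bad = set(celldata) - _CELL_KEYS
    if bad:
        raise ConfigError(f"unknown protocell keys: {sorted(bad)}")
    cfg.n_cells = celldata.get("n_cells", cfg.n_cells)
    cfg.mode = celldata.get("mode", cfg.mode)
    cfg.protocell_cycles = celldata.get("cycles", cfg.protocell_cycles)
    if cfg.mode not in ("none", "ligase", "polymerase"):
        raise ConfigError(f"unknown selection mode {cfg.mode!r}")
    return cfg


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; an empty file gives
    the full standard defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such configuration file: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    cfg = config_from_dict(data)
    log.info("loaded configuration from %s: %s", path, cfg.to_dict())
    return cfg


# ---------------------------------------------------------------------------
# FASTA and snapshots
# ---------------------------------------------------------------------------

def strand_record(strand: Strand, cycle: Optional[int] = None) -> SeqRecord:
    desc = f"len={strand.n} n_start={strand.n_start} stalled={int(strand.stalled_3p)}"
    if cycle is not None:
        desc = f"cycle={cycle} " + desc
    return SeqRecord(Seq(strand.seq), id=f"s{strand.id}", description=desc)


def write_fasta(strands: List[Strand], path, cycle: Optional[int] = None) -> None:
    """Write a strand population as FASTA (ids plus cycle/length fields)."""
    SeqIO.write([strand_record(s, cycle) for s in strands], str(path), "fasta")


def read_fasta_sequences(path) -> List[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_snapshot(mixture: Mixture, fasta_path, sidecar_path) -> None:
    """Serialize a mixture: strands as FASTA, helices plus monomer counts
    as a tab-separated sidecar."""
    write_fasta(sorted(mixture.strands.values(), key=lambda s: s.id), fasta_path)
    with open(sidecar_path, "w") as fh:
        for b in BASES:
            fh.write(f"# monomers\t{b}\t{mixture.monomers[b]}\n")
        fh.write("helix_id\tstrand_a\tstrand_b\tstart_a\tstart_b\tlength\n")
        for hid in sorted(mixture.helices):
            h = mixture.helices[hid]
            fh.write(f"{h.id}\t{h.strand_a}\t{h.strand_b}"
                     f"\t{h.start_a}\t{h.start_b}\t{h.length}\n")


def read_snapshot(fasta_path, sidecar_path) -> Mixture:
    """Reconstruct a mixture from a snapshot; helices referencing missing
    strands raise an integrity error."""
    mixture = Mixture()
    max_id = -1
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid = int(rec.id.lstrip("s"))
        fields = dict(part.split("=", 1) for part in rec.description.split()
                      if "=" in part)
        strand = Strand(sid, str(rec.seq),
                        n_start=int(fields.get("n_start", len(rec.seq))),
                        stalled_3p=bool(int(fields.get("stalled", 0))))
        mixture.strands[sid] = strand
        cid = mixture._next_cluster_id
        mixture._next_cluster_id += 1
        mixture.clusters[cid] = Cluster(cid, {sid}, set())
        mixture.cluster_of[sid] = cid
        max_id = max(max_id, sid)
    mixture._next_strand_id = max_id + 1
    helices = []
    with open(sidecar_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# monomers"):
                _, base, count = line.split("\t")
                mixture.monomers[base] = int(count)
                continue
            if line.startswith("helix_id"):
                continue
            hid, sa, sb, pa, pb, length = (int(x) for x in line.split("\t"))
            helices.append((hid, sa, sb, pa, pb, length))
    for hid, sa, sb, pa, pb, length in helices:
        if sa not in mixture.strands or sb not in mixture.strands:
            raise InconsistentStateError(
                f"helix {hid} references a strand missing from the snapshot")
        helix = mixture.add_helix(sa, sb, pa, pb, length)
        # preserve the original helix id
        auto_id = helix.id
        mixture.helices.pop(auto_id)
        helix.id = hid
        mixture.helices[hid] = helix
        cluster = mixture.clusters[mixture.cluster_of[sa]]
        cluster.helix_ids.discard(auto_id)
        cluster.helix_ids.add(hid)
    mixture._next_helix_id = max((h + 1 for h, *_ in helices), default=0)
    mixture.check_invariants()
    return mixture
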
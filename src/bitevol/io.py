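"""File formats: binary-alphabet FASTA dialect, event logs, manifests.

Genomes are serialized in a FASTA dialect over the alphabet {0,1}, one record
per individual, with a structured header ``>id gen=<g> fit=<f>``; round-trips
are bit-exact.  Replication event logs are tab-separated text with one line
per event.  Tabular metrics go through pandas CSV elsewhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome import Genome, MutationEvent, MutationType

__all__ = [
    "write_genomes",
    "read_genomes",
    "write_event_log",
    "read_event_log",
    "write_manifest",
    "read_manifest",
    "write_bed",
]

_WRAP = 70

EVENT_LOG_HEADER = "generation\ttype\tp1\tp2\tp3\tsize\tpayload"


def write_genomes(
    path: str | Path,
    records: Iterable[tuple[str, int, float, Genome | np.ndarray]],
) -> None:
    """Write ``(id, generation, fitness, genome)`` records."""
    with open(path, "w") as fh:
        for rid, gen, fit, g in records:
            bits = g.bits if isinstance(g, Genome) else np.asarray(g)
            s = "".join("01"[int(b)] for b in bits)
            fh.write(f">{rid} gen={gen} fit={fit!r}\n")
            for i in range(0, len(s), _WRAP):
                fh.write(s[i : i + _WRAP] + "\n")


def read_genomes(path: str | Path) -> list[tuple[str, int, float, Genome]]:
    out: list[tuple[str, int, float, Genome]] = []
    rid, gen, fit, chunks = None, 0, 0.0, []

    def flush():
        if rid is not None:
            out.append((rid, gen, fit, Genome.from_string("".join(chunks))))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                rid = fields[0]
                kv = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
                gen = int(kv.get("gen", 0))
                fit = float(kv.get("fit", "nan"))
                chunks = []
            else:
                chunks.append(line)
    flush()
    return out


def write_event_log(
    path: str | Path, events: Iterable[tuple[int, MutationEvent]]
) -> None:
    """One line per event: ``generation type p1 p2 p3 size payload``."""
    with open(path, "w") as fh:
        fh.write(EVENT_LOG_HEADER + "\n")
        for gen, ev in events:
            payload = (
                "".join("01"[int(b)] for b in ev.payload)
                if ev.payload is not None
                else "."
            )
            name = ev.mtype.name.lower()
            if ev.mtype == MutationType.TRANSLOCATION and ev.inverted:
                name += "_inv"
            if ev.discarded:
                name += "!"
            fh.write(
                f"{gen}\t{name}\t{ev.p1}\t{ev.p2}\t{ev.p3}\t{ev.size}\t{payload}\n"
            )


def read_event_log(path: str | Path) -> list[tuple[int, MutationEvent]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != EVENT_LOG_HEADER:
            raise ValueError("not an event log")
        for line in fh:
            gen, name, p1, p2, p3, size, payload = line.rstrip("\n").split("\t")
            discarded = name.endswith("!")
            name = name.rstrip("!")
            inverted = name.endswith("_inv")
            name = name.removesuffix("_inv")
            ev = MutationEvent(
                mtype=MutationType[name.upper()],
                p1=int(p1),
                p2=int(p2),
                p3=int(p3),
                size=int(size),
                payload=None
                if payload == "."
                else np.frombuffer(payload.encode(), np.uint8) - ord("0"),
                inverted=inverted,
                discarded=discarded,
            )
            # the generation field may carry a composite "gen:cell" tag
            out.append((int(gen) if gen.isdigit() else gen, ev))
    return out


def write_bed(path: str | Path, name: str, intervals: list[tuple[int, int, str]]):
    """BED-like 0-based half-open CDS intervals with a strand column."""
    with open(path, "w") as fh:
        for i, (start, end, strand) in enumerate(intervals):
            fh.write(f"{name}\t{start}\t{end}\tcds_{i}\t0\t{strand}\n")


def config_digest(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
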
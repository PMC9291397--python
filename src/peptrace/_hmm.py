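"""Thin wrappers around pyhmmer used by the catalog and proximity modules.

All searches run single-threaded with an explicit database size ``Z`` so
that E-values are deterministic and comparable between runs regardless of
how the caller batches queries.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from pyhmmer import easel, plan7, hmmer

ALPHABET = easel.Alphabet.amino()
_BACKGROUND = plan7.Background(ALPHABET)


def as_str(name) -> str:
    return name.decode() if isinstance(name, (bytes, bytearray)) else str(name)


def digitize(name: str, sequence: str) -> easel.DigitalSequence:
    return easel.TextSequence(name=name.encode(), sequence=sequence).digitize(ALPHABET)


def digitize_many(items: Iterable[tuple[str, str]]) -> list[easel.DigitalSequence]:
    return [digitize(n, s) for n, s in items]


def build_hmm_from_sequence(name: str, sequence: str) -> plan7.HMM:
    """Single-sequence profile (the ``hmmbuild`` one-sequence path)."""
    builder = plan7.Builder(ALPHABET)
    hmm, _, _ = builder.build(digitize(name, sequence), _BACKGROUND)
    hmm.name = name.encode()
    return hmm


def build_hmm_from_msa(name: str, msa: easel.TextMSA) -> plan7.HMM:
    dmsa = msa.digitize(ALPHABET)
    dmsa.name = name.encode()
    builder = plan7.Builder(ALPHABET)
    hmm, _, _ = builder.build_msa(dmsa, _BACKGROUND)
    hmm.name = name.encode()
    return hmm


def align_to_hmm(hmm: plan7.HMM, items: Sequence[tuple[str, str]]) -> easel.TextMSA:
    """hmmalign: align sequences to a profile; one column set for all rows."""
    return hmmer.hmmalign(hmm, digitize_many(items))


def phmmer_search(queries: Sequence[tuple[str, str]],
                  targets: Sequence[tuple[str, str]],
                  evalue_report: float = 10.0):
    """Run phmmer (sequence vs. sequence database).

    Yields ``(query_name, TopHits)`` pairs; Z is pinned to the database size.
    """
    dig_t = digitize_many(targets)
    dig_q = digitize_many(queries)
    z = max(len(dig_t), 1)
    for q, hits in zip(dig_q, hmmer.phmmer(dig_q, dig_t, cpus=1, Z=z, E=evalue_report)):
        yield as_str(q.name), hits


def hmmsearch_many(hmms: Sequence[plan7.HMM],
                   targets: Sequence[tuple[str, str]],
                   evalue_report: float = 10.0):
    """Run hmmsearch (profile vs. sequence database); yields (hmm name, TopHits)."""
    dig_t = digitize_many(targets)
    z = max(len(dig_t), 1)
    for hmm, hits in zip(hmms, hmmer.hmmsearch(hmms, dig_t, cpus=1, Z=z, E=evalue_report)):
        yield as_str(hmm.name), hits


def query_coverage(hit, query_length: int) -> float:
    """Fraction of the query/profile positions covered by the hit's domains."""
    covered: set[int] = set()
    for dom in hit.domains:
        ali = dom.alignment
        covered.update(range(ali.hmm_from, ali.hmm_to + 1))
    return len(covered) / query_length if query_length else 0.0
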
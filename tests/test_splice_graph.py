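"""Event collection, boundary calling, partial exons, graph and phasing."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from isoforge.alignment_io import ReadClass
from isoforge.splice_graph import (
    ACCEPTOR,
    DONOR,
    END_3P,
    START_5P,
    Event,
    build_graph,
    call_boundaries,
    collect_positions,
    extract_phasing_paths,
    segment_partial_exons,
)

from conftest import FIG_EXONS, make_bundle, make_record


class TestCollectPositions:
    def test_full_length_two_exon_read(self):
        rec = make_record("r", [(0, 100), (200, 300)], read_class=ReadClass.FULL_LENGTH)
        events = collect_positions(make_bundle([rec]))
        assert events == [
            Event(0, START_5P),
            Event(100, DONOR),
            Event(200, ACCEPTOR),
            Event(300, END_3P),
        ]

    def test_internal_read_contributes_splice_events_only(self):
        rec = make_record("r", [(0, 100), (200, 300)], read_class=ReadClass.NFL_INTERNAL)
        events = collect_positions(make_bundle([rec]))
        assert [e.kind for e in events] == [DONOR, ACCEPTOR]

    def test_splice_sorts_before_boundary_at_equal_position(self):
        # a 3' end exactly at another read's donor position
        r1 = make_record("r1", [(0, 100)], read_class=ReadClass.NFL_3ONLY)
        r2 = make_record("r2", [(50, 100), (200, 260)], read_class=ReadClass.NFL_INTERNAL)
        events = collect_positions(make_bundle([r1, r2]))
        at_100 = [e.kind for e in events if e.pos == 100]
        assert at_100 == [DONOR, END_3P]

    def test_matches_per_read_enumeration(self, sim_bundles):
        for bundle in sim_bundles:
            expected: Counter = Counter()
            for rec in bundle.records:
                for d, a in rec.junctions:
                    expected[(d, DONOR)] += 1
                    expected[(a, ACCEPTOR)] += 1
                if rec.read_class in (ReadClass.FULL_LENGTH, ReadClass.NFL_5ONLY):
                    pos = rec.end if rec.strand == "-" else rec.start
                    expected[(pos, START_5P)] += 1
                if rec.read_class in (ReadClass.FULL_LENGTH, ReadClass.NFL_3ONLY):
                    pos = rec.start if rec.strand == "-" else rec.end
                    expected[(pos, END_3P)] += 1
            got = Counter((e.pos, e.kind) for e in collect_positions(bundle))
            assert got == expected


class TestCallBoundaries:
    def test_three_concordant_reads_call_leftmost(self):
        events = [Event(100, START_5P), Event(102, START_5P), Event(103, START_5P)]
        calls = call_boundaries(events, min_boundary_reads=3)
        assert len(calls) == 1
        assert (calls[0].kind, calls[0].position, calls[0].support) == (START_5P, 100, 3)

    def test_two_reads_below_threshold_yield_nothing(self):
        events = [Event(100, START_5P), Event(102, START_5P)]
        assert call_boundaries(events, min_boundary_reads=3) == []

    def test_splice_event_breaks_the_run(self):
        events = [
            Event(500, END_3P),
            Event(501, END_3P),
            Event(502, DONOR),
            Event(503, END_3P),
        ]
        assert call_boundaries(events, min_boundary_reads=3) == []
        calls = call_boundaries(events, min_boundary_reads=2)
        assert len(calls) == 1
        assert (calls[0].kind, calls[0].position) == (END_3P, 501)  # rightmost 3'

    def test_other_boundary_type_breaks_the_run(self):
        events = [
            Event(100, START_5P),
            Event(101, START_5P),
            Event(102, END_3P),
            Event(103, START_5P),
        ]
        assert call_boundaries(events, min_boundary_reads=3) == []

    def test_spacing_beyond_allowance_splits_runs(self):
        events = [Event(p, START_5P) for p in (100, 105, 200, 203, 206)]
        calls = call_boundaries(events, min_boundary_reads=3, boundary_allowance=10)
        assert [(c.position, c.support) for c in calls] == [(200, 3)]

    def test_reverse_strand_five_prime_reports_rightmost(self):
        events = [Event(p, START_5P) for p in (100, 102, 103)]
        calls = call_boundaries(events, min_boundary_reads=3, strand="-")
        assert calls[0].position == 103

    def test_raising_threshold_never_creates_calls(self):
        # monotonicity over random event streams
        rng = np.random.default_rng(5)
        kinds = [DONOR, ACCEPTOR, START_5P, END_3P]
        for _ in range(40):
            events = sorted(
                (
                    Event(int(p), kinds[int(k)])
                    for p, k in zip(
                        rng.integers(0, 300, 30), rng.integers(0, 4, 30)
                    )
                ),
                key=lambda e: (e.pos, 0 if e.is_splice else 1),
            )
            prev = None
            for threshold in (1, 2, 3, 4):
                calls = {
                    (c.kind, c.position)
                    for c in call_boundaries(events, min_boundary_reads=threshold)
                }
                if prev is not None:
                    assert calls <= prev
                prev = calls

    def test_run_scan_matches_regex_oracle(self):
        # encode the typed event stream as a string and find runs by regex
        import re

        rng = np.random.default_rng(9)
        kinds = [DONOR, START_5P, END_3P]
        symbols = {DONOR: "s", START_5P: "F", END_3P: "T"}
        for _ in range(40):
            positions = np.sort(rng.integers(0, 60, 25))
            events = [
                Event(int(p), kinds[int(k)])
                for p, k in zip(positions, rng.integers(0, 3, 25))
            ]
            events.sort(key=lambda e: (e.pos, 0 if e.is_splice else 1))
            # allowance large enough that only type interruptions matter
            calls = call_boundaries(events, min_boundary_reads=3, boundary_allowance=100)
            text = "".join(symbols[e.kind] for e in events)
            expected = []
            for m in re.finditer(r"(F{3,}|T{3,})", text):
                run = [events[i] for i in range(m.start(), m.end())]
                kind = run[0].kind
                pos = run[0].pos if kind == START_5P else run[-1].pos
                expected.append((kind, pos, len(run)))
            got = [(c.kind, c.position, c.support) for c in calls]
            assert got == expected


class TestPartialExons:
    def test_single_uncovered_gapless_read(self):
        bundle = make_bundle([make_record("r", [(0, 100)])])
        exons = segment_partial_exons(bundle)
        assert len(exons) == 1
        assert (exons[0].start, exons[0].end, exons[0].weight) == (0, 100, 1.0)

    def test_worked_example_yields_five_partial_exons(self, fig1_bundle):
        exons = segment_partial_exons(fig1_bundle)
        assert [(e.start, e.end) for e in exons] == sorted(FIG_EXONS.values())

    def test_weights_match_pileup_oracle(self, sim_bundles):
        for bundle in sim_bundles:
            exons = segment_partial_exons(bundle)
            lo = min(r.start for r in bundle.records)
            hi = max(r.end for r in bundle.records)
            pile = np.zeros(hi - lo)
            for rec in bundle.records:
                for s, e in rec.segments:
                    pile[s - lo : e - lo] += 1
            for px in exons:
                assert px.weight == pytest.approx(
                    pile[px.start - lo : px.end - lo].mean()
                )
            # pieces tile the covered genome exactly
            covered = int((pile > 0).sum())
            assert sum(e.end - e.start for e in exons) == covered


class TestBuildGraph:
    def test_single_exon_bundle_is_source_vertex_sink(self):
        bundle = make_bundle([make_record("r", [(0, 100)])])
        exons = segment_partial_exons(bundle)
        graph = build_graph(bundle, exons)
        assert [(u, v, e.kind) for u, v, e in graph.edges()] == [
            (graph.s, 0, "source_link"),
            (0, graph.t, "sink_link"),
        ]

    def test_worked_example_structure(self, fig1_bundle):
        exons = segment_partial_exons(fig1_bundle)
        graph = build_graph(fig1_bundle, exons)
        # vertices a..e = 0..4; junctions a-c, b-c, c-d, c-e with read counts
        junctions = {
            (u, v): e.weight for u, v, e in graph.edges() if e.kind == "junction"
        }
        assert junctions == {(0, 2): 1.0, (1, 2): 2.0, (2, 3): 2.0, (2, 4): 1.0}
        sources = {v for u, v, e in graph.edges() if u == graph.s}
        sinks = {u for u, v, e in graph.edges() if v == graph.t}
        assert sources == {0, 1} and sinks == {3, 4}

    def test_edge_weights_match_read_census(self, sim_bundles):
        for bundle in sim_bundles:
            from isoforge.splice_graph import call_boundaries as cb, collect_positions as cp

            boundaries = cb(cp(bundle), strand=bundle.strand)
            exons = segment_partial_exons(bundle, boundaries)
            graph = build_graph(bundle, exons, boundaries)
            junction_census: Counter = Counter()
            for rec in bundle.records:
                junction_census.update(rec.junctions)
            for u, v, e in graph.edges():
                if e.kind == "junction":
                    donor = graph.vertices[u].end
                    acceptor = graph.vertices[v].start
                    assert e.weight == junction_census[(donor, acceptor)]
                elif e.kind == "adjacency":
                    boundary = graph.vertices[v].start
                    crossing = sum(
                        1
                        for rec in bundle.records
                        if any(s < boundary < t for s, t in rec.segments)
                    )
                    assert e.weight == crossing
            # conservation: junction edge weights sum to junction observations
            total = sum(
                e.weight for _, _, e in graph.edges() if e.kind == "junction"
            )
            assert total == sum(junction_census.values())

    def test_every_vertex_on_an_s_t_path(self, sim_bundles):
        for bundle in sim_bundles:
            exons = segment_partial_exons(bundle)
            graph = build_graph(bundle, exons)
            # forward reachability from s
            reach = {graph.s}
            for v in graph.topological_order()[1:]:
                if any(u in reach for u, _ in graph.in_edges(v)):
                    reach.add(v)
            co = {graph.t}
            for u in reversed(graph.topological_order()[:-1]):
                if any(v in co for v, _ in graph.out_edges(u)):
                    co.add(u)
            for v in range(graph.n_vertices):
                assert v in reach and v in co


class TestPhasingPaths:
    def test_worked_example_paths(self, fig1_bundle):
        exons = segment_partial_exons(fig1_bundle)
        graph = build_graph(fig1_bundle, exons)
        paths = extract_phasing_paths(fig1_bundle, graph)
        assert {p.vertices: p.support for p in paths} == {(0, 2, 4): 1, (1, 2, 3): 2}

    def test_two_exon_read_contributes_no_path(self):
        bundle = make_bundle(
            [make_record("r", [(0, 100), (200, 300)])]
        )
        exons = segment_partial_exons(bundle)
        graph = build_graph(bundle, exons)
        assert extract_phasing_paths(bundle, graph) == []

    def test_chains_increase_in_coordinate_order(self, sim_bundles):
        for bundle in sim_bundles:
            exons = segment_partial_exons(bundle)
            graph = build_graph(bundle, exons)
            for p in extract_phasing_paths(bundle, graph):
                assert list(p.vertices) == sorted(p.vertices)
                assert len(p.vertices) >= 3

    def test_matches_naive_projection_oracle(self, sim_bundles):
        for bundle in sim_bundles:
            exons = segment_partial_exons(bundle)
            graph = build_graph(bundle, exons)
            expected: Counter = Counter()
            for rec in bundle.records:
                chain = tuple(
                    i
                    for i, v in enumerate(graph.vertices)
                    if any(s < v.end and v.start < e for s, e in rec.segments)
                )
                # oracle compatibility: walk the chain and demand the read's
                # own junction or contiguous coverage between neighbours
                ok = len(chain) >= 3
                for a, b in zip(chain, chain[1:]):
                    u, v = graph.vertices[a], graph.vertices[b]
                    if u.end == v.start:
                        ok = ok and any(s < u.end < e for s, e in rec.segments)
                    else:
                        ok = ok and (u.end, v.start) in set(rec.junctions)
                for idx in chain[1:-1]:
                    v = graph.vertices[idx]
                    ok = ok and any(
                        s <= v.start and v.end <= e for s, e in rec.segments
                    )
                if ok:
                    expected[chain] += 1
            got = {p.vertices: p.support for p in extract_phasing_paths(bundle, graph)}
            assert got == dict(expected)
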
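"""Shared helpers for building small graphs in tests."""

from difnet import CoexpressionNetwork, Edge


def net_from_pairs(nodes, pairs, label="x") -> CoexpressionNetwork:
    edges = tuple(
        Edge(*sorted(p), r=0.9, p_value=1e-6, q_value=1e-5, sign="positive")
        for p in sorted(pairs)
    )
    return CoexpressionNetwork(label, tuple(sorted(nodes)), edges, n_samples=10)
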
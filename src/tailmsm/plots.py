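"""Headless-safe plotting of ITS curves, CK panels, free-energy surfaces
and kinetic networks.  All functions accept an output path and write PNG."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_its(its, path) -> None:
    """Implied timescales vs lag, log time axis, grey below-resolution wedge."""
    fig, ax = plt.subplots(figsize=(5, 4))
    lags_ns = its.lags * its.dt_ns
    for j in range(its.m):
        ax.plot(lags_ns, its.timescales_ns[:, j], "o-", label=f"t{j + 2}")
    ax.fill_between(lags_ns, 0, lags_ns, color="0.8", zorder=0)
    ax.set_yscale("log")
    ax.set_xlabel("lag time (ns)")
    ax.set_ylabel("implied timescale (ns)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ck(ck, path) -> None:
    """Estimated vs predicted set-to-set probabilities per (A, B) pair."""
    m = len(ck.sets)
    fig, axes = plt.subplots(m, m, figsize=(2.2 * m, 2.0 * m),
                             sharex=True, sharey=True, squeeze=False)
    ks = np.asarray([0] + list(ck.multiples))
    for a in range(m):
        for b in range(m):
            ax = axes[a][b]
            start = 1.0 if a == b else 0.0
            pred = [start] + [ck.predicted[k][a, b] for k in ck.multiples]
            est = [start] + [ck.estimated[k][a, b] for k in ck.multiples]
            err = [0.0] + [ck.stderr[k][a, b] for k in ck.multiples]
            ax.plot(ks * ck.lagtime * ck.dt_ns, pred, "k--", label="predicted")
            ax.errorbar(ks * ck.lagtime * ck.dt_ns, est, yerr=err, fmt="o",
                        ms=3, label="estimated")
            ax.set_title(f"{a + 1} -> {b + 1}", fontsize=8)
            ax.set_ylim(-0.05, 1.05)
    axes[0][0].legend(fontsize=7)
    fig.supxlabel("time (ns)")
    fig.supylabel("probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fes(fes, path) -> None:
    """Filled-contour free-energy surface (kcal/mol) over (IC1, IC2)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
    yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
    Z = np.ma.masked_invalid(fes.delta_g).T
    cs = ax.contourf(xc, yc, Z, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax, label=r"$\Delta G$ (kcal/mol)")
    ax.set_xlabel("IC1")
    ax.set_ylabel("IC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_network(summary, path) -> None:
    """Kinetic network: node size ~ population, arrow width ~ rate."""
    import networkx as nx
    from .kinetics import export_network

    G = export_network(summary)
    fig, ax = plt.subplots(figsize=(5, 5))
    pos = nx.circular_layout(G)
    sizes = [120 + 25 * G.nodes[n]["population_pct"] for n in G.nodes]
    nx.draw_networkx_nodes(G, pos, node_size=sizes, node_color="#7fb2d5", ax=ax)
    nx.draw_networkx_labels(
        G, pos,
        {n: f'{G.nodes[n]["label"]}\n{G.nodes[n]["population_pct"]:.0f}%'
         for n in G.nodes}, font_size=7, ax=ax)
    widths = [G.edges[e]["penwidth"] for e in G.edges]
    nx.draw_networkx_edges(G, pos, width=widths, connectionstyle="arc3,rad=0.15",
                           ax=ax)
    nx.draw_networkx_edge_labels(
        G, pos, {e: f'{G.edges[e]["mfpt_ns"]:.3g} ns' for e in G.edges},
        font_size=6, ax=ax)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
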
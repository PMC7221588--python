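"""Marginal ML ancestral sequence reconstruction.

For every internal node and alignment column, the posterior distribution
over the 20 amino acids given the whole alignment, the tree with its branch
lengths, and the substitution model.  Reconstructions are summarized by the
maximum-a-posteriori (MAP) state and its probability; downstream analyses
keep only sites whose MAP probability clears a confidence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import PruningContext
from .io import AMINO_ACIDS, Phylogeny, ProteinAlignment
from .models import GammaRates, SubstModel


@dataclass
class AncestralStates:
    """Per-internal-node, per-site posteriors over amino acids.

    ``posteriors[node_id]`` is an (L, 20) array summing to 1 per site;
    ``map_state``/``map_prob`` give the argmax residue and its probability.
    """

    node_ids: list[int]
    posteriors: dict[int, np.ndarray]
    map_state: dict[int, np.ndarray]  # per node: length-L array of residues
    map_prob: dict[int, np.ndarray]

    def sequence(self, node_id: int) -> str:
        return "".join(self.map_state[node_id])

    def masked_sequence(
        self, node_id: int, threshold: float = 0.5, inclusive: bool = False
    ) -> str:
        """MAP sequence with low-confidence sites masked as 'x'.

        A site is kept when its MAP probability exceeds the threshold
        (strictly, by default); ``inclusive=True`` keeps ties.
        """
        probs = self.map_prob[node_id]
        keep = probs >= threshold if inclusive else probs > threshold
        return "".join(
            s if ok else "x" for s, ok in zip(self.map_state[node_id], keep)
        )


def marginal_ancestral(
    aln: ProteinAlignment,
    tree: Phylogeny,
    model: SubstModel,
    rates: GammaRates,
) -> AncestralStates:
    """Marginal posteriors at every internal node via the up–down algorithm.

    Per-category posteriors are mixed by each category's per-site posterior
    weight (empirical Bayes over the discrete-Gamma mixture).  Deterministic:
    argmax ties resolve to the lowest amino-acid index in the canonical
    ordering.
    """
    ctx = PruningContext(aln, tree, model, rates)
    ctx.down()
    ctx.up()
    residues = np.array(list(AMINO_ACIDS))
    node_ids, posteriors, map_state, map_prob = [], {}, {}, {}
    for node in tree.postorder():
        if node.is_leaf:
            continue
        post = ctx.node_posteriors(node.index)
        idx = post.argmax(axis=1)
        node_ids.append(node.index)
        posteriors[node.index] = post
        map_state[node.index] = residues[idx]
        map_prob[node.index] = post[np.arange(post.shape[0]), idx]
    return AncestralStates(node_ids, posteriors, map_state, map_prob)


def ancestral_sequence_report(
    anc: AncestralStates, threshold: float = 0.5, inclusive: bool = False
) -> pd.DataFrame:
    """Tidy per-node, per-site table of MAP states with masking applied."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    rows = []
    for node_id in anc.node_ids:
        masked = anc.masked_sequence(node_id, threshold, inclusive)
        for site, (state, prob, shown) in enumerate(
            zip(anc.map_state[node_id], anc.map_prob[node_id], masked), start=1
        ):
            rows.append(
                {
                    "node": node_id,
                    "site": site,
                    "map_state": state,
                    "map_prob": float(prob),
                    "masked": shown == "x",
                }
            )
    return pd.DataFrame(rows)
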
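"""CAREMIL: attention-based multiple-instance learning with summary-statistic
class tokens for slide-level classification of cell-embedding bags."""

__version__ = "0.1.0"

from .aggregators import (AggregatorConfig, SummaryTokens, build_summary_tokens,
                          generalized_mean_aggregate, mean_aggregate,
                          variance_aggregate)
from .bags import (DEFAULT_CELL_TYPES, DEFAULT_CLASSES, CellBag, CohortSplit,
                   CompositionVector, SlideRecord, composition_vector,
                   load_cohort, save_cohort, split_by_patient)
from .explain import (CellRanking, EnrichmentTable, PanelSelection,
                      enrichment_table, marker_overlap, rank_cells,
                      select_panel, top_fraction_set)
from .gated import GatedMilConfig, GatedMilModel, gated_attention_weights, gated_forward
from .model import (AttentionReport, CaremilConfig, CaremilModel,
                    extract_cell_attention, forward, initialize, load_model,
                    predict_proba, save_model)
from .synthetic import (MarkerSpec, SyntheticCohortConfig, default_cohort_config,
                        extract_pools, generate_cohort, lod_experiment,
                        make_prototypes, marker_flags, mix_synthetic_patient,
                        sample_bag, two_class_config)
from .training import (BlastBinTable, TaskSpec, TrainConfig, auroc,
                       cytometry_baseline, evaluate_auroc,
                       sensitivity_by_blast_bin, train_model)
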
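"""ehgpredict: EHG feature extraction and preterm-birth prediction.

A tested re-implementation of a preterm-birth prediction pipeline from
electrohysterogram (EHG) signals: 46 linear/non-linear/entropy features
per channel (including dispersion and bubble entropy), internal-parameter
optimization of the entropy estimators by class separability, SMOTE
class balancing, LDA classification over 30 stratified holdout
partitions, and genetic-algorithm wrapper feature selection with a
parsimony-weighted F1 fitness.  A synthetic-EHG generator with known
ground truth stands in for the clinical Physionet recordings.
"""

from .preprocess import (BANDS, CHANNELS, FWH, MISSING, WBW, BandSpec,
                         EHGRecord, WindowSet, aggregate_median,
                         artifact_free_segments, read_cohort, read_record,
                         segment_windows, write_cohort, zero_phase_bandpass)
from .synthetic import (PRETERM, TERM, ClassSignalParams, SynthCohortParams,
                        gen_cohort, gen_feature_table, gen_record)
from .linear import (PSD, peak_to_peak, spectral_feature_set, teager_energy,
                     welch_psd)
from .complexity import (katz_fd, lempel_ziv, poincare_metrics,
                         time_reversibility)
from .entropy import (EntropyParams, EntropySweepResult, bubble_entropy,
                      dispersion_entropy, fuzzy_entropy,
                      optimize_entropy_params, parameter_grid, sample_entropy,
                      spectral_entropy, sweep_entropy)
from .reference_params import REFERENCE_ENTROPY_PARAMS, get_entropy_params
from .features import (all_feature_columns, ehg_feature_names,
                       extract_channel_features, extract_feature_table)
from .stats import TestResult, friedman_test, holm_correction, ranksum_test
from .pipeline import (EXPECTED_DIMS, MODEL_ACRONYMS, FeatureTable, LDAModel,
                       MetricsReport, ModelSpec, PartitionSet,
                       balance_and_partition, build_feature_matrix,
                       classification_metrics, compare_models, evaluate_model,
                       evaluate_model_train_smote, lda_fit, make_partitions,
                       smote_balance)
from .ga import (GAConfig, GARunResult, FitnessEvaluator, evolve_generation,
                 exhaustive_best_mask, fitness, run_ga)

__version__ = "0.1.0"
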
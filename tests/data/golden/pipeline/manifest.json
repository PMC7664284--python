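{
  "config": {
    "exclusion": {
      "acquisition_filter_both_groups": true,
      "beta_filter_both_groups": false,
      "beta_sd": 3.0,
      "reversal_filter_both_groups": false,
      "score_sd": 1.5
    },
    "fit": {
      "beta_max": 50.0,
      "n_restarts": 10,
      "q_init": 0.5,
      "seed": 0,
      "tol": 1e-06
    },
    "replication_mode": true,
    "seed": 0,
    "task": {
      "miss_probability": 0.0,
      "n_trials": 120,
      "p_reward_advantageous": 0.8,
      "p_reward_disadvantageous": 0.2,
      "reversal_trial": 60,
      "schedule_mode": "exact_ratio"
    }
  },
  "config_hash": "4f6d7d9ebee322f9",
  "package_version": "0.1.0",
  "seed": 0,
  "stage_counts": {
    "included": 4,
    "input": 6,
    "post_score_filter": 6,
    "post_strategy_filter": 4
  },
  "warnings": [
    "C003: Q-learning fit at a parameter bound"
  ]
}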
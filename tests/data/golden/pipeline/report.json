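{
  "cutoff_used": 0.512,
  "funnel": {
    "included": 4,
    "input": 6,
    "post_score_filter": 6,
    "post_strategy_filter": 4
  },
  "group_summary": [
    {
      "ALS_summary": "86.50 (2.12)",
      "control_summary": "78.00 (14.14)",
      "p_value": 1.0,
      "significant": false,
      "statistic": 2.5,
      "test": "mannwhitney",
      "variable": "total_score"
    },
    {
      "ALS_summary": "44.00 (1.41)",
      "control_summary": "39.50 (9.19)",
      "p_value": 1.0,
      "significant": false,
      "statistic": 2.0,
      "test": "mannwhitney",
      "variable": "acquisition_score"
    },
    {
      "ALS_summary": "42.50 (0.71)",
      "control_summary": "38.50 (4.95)",
      "p_value": 0.4142161782,
      "significant": false,
      "statistic": 3.5,
      "test": "mannwhitney",
      "variable": "reversal_score"
    },
    {
      "ALS_summary": "0.19 (0.01)",
      "control_summary": "0.19 (0.00)",
      "p_value": 1.0,
      "significant": false,
      "statistic": 2.0,
      "test": "mannwhitney",
      "variable": "alpha"
    },
    {
      "ALS_summary": "11.05 (4.48)",
      "control_summary": "4.29 (4.66)",
      "p_value": 0.3333333333,
      "significant": false,
      "statistic": 4.0,
      "test": "mannwhitney",
      "variable": "beta"
    }
  ],
  "logistic_model": {
    "coef_alpha": -1.263,
    "coef_beta": 0.245,
    "intercept": -0.742,
    "printed_form": "P_ab = 1 / (1 + exp(+0.742 +1.263*alpha -0.245*beta))",
    "separation": false,
    "source": "paper_fixed"
  },
  "model_comparison": [
    {
      "aic": 9.5349506355,
      "best": false,
      "k": 2,
      "loglik": -2.7674753178,
      "model": "alpha_only",
      "separation": false
    },
    {
      "aic": 4.0,
      "best": true,
      "k": 2,
      "loglik": -0.0,
      "model": "beta_only",
      "separation": true
    },
    {
      "aic": 6.0001328052,
      "best": false,
      "k": 3,
      "loglik": -6.64026e-05,
      "model": "alpha_and_beta",
      "separation": true
    }
  ],
  "n_anomalous_als": 2,
  "roc": {
    "auc": 1.0,
    "optimal_cutoff": 0.705166345611875,
    "sensitivity_at_cutoff": 1.0,
    "specificity_at_cutoff": 1.0
  }
}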
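{
  "extra_trees": {"n_estimators": [200], "max_features": ["sqrt", 1.0], "min_samples_leaf": [1, 2]},
  "gradient_boosting": {"n_estimators": [200], "learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
  "xgb": {"n_estimators": [200], "learning_rate": [0.05, 0.1], "max_depth": [3, 5]},
  "random_forest": {"n_estimators": [200], "max_features": ["sqrt", 1.0]},
  "knn": {"n_neighbors": [3, 5, 7]},
  "adaboost": {"n_estimators": [100], "learning_rate": [0.5, 1.0]},
  "decision_tree": {"max_depth": [null, 5, 10]},
  "ridge": {"alpha": [0.1, 1.0, 10.0]},
  "elastic_net": {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.5]},
  "bayesian_ridge": {},
  "lasso": {"alpha": [0.01, 0.1, 1.0]}
}
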
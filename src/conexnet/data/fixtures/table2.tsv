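module	mirna	kme_all	p_kme_all	kme_control	p_kme_control	kme_linseed	p_kme_linseed	kme_safflower	p_kme_safflower
Blue	bta-miR-30d	0.93	1.58e-22	0.96	5.06e-7	0.95	1.24e-6	0.93	1.69e-5
Blue	bta-miR-96	0.89	1.62e-15	0.89	6.36e-5	0.90	2.62e-5	0.90	6.64e-5
Blue	bta-miR-191	0.87	4.00e-20	0.93	5.88e-6	0.97	9.66e-8	0.87	2.89e-4
Blue	bta-miR-151-5p	0.83	1.04e-14	0.90	2.68e-5	0.92	1.50e-5	0.83	7.43e-4
Blue	bta-miR-409a	0.80	6.90e-12	0.85	2.47e-4	0.80	9.23e-4	0.89	1.10e-4
Blue	bta-miR-183	0.77	4.79e-13	0.90	4.18e-5	0.77	1.79e-3	0.91	5.11e-5
Blue	bta-miR-99a-5p	0.77	1.49e-14	0.91	1.82e-5	0.77	1.79e-3	0.94	1.20e-5
Blue	bta-let-7b	0.76	1.66e-9	0.76	2.24e-3	0.80	8.20e-4	0.84	6.75e-4
Blue	bta-miR-2285k	0.75	2.89e-9	0.75	2.29e-3	0.75	2.71e-3	0.86	2.96e-4
Blue	bta-miR-652	0.73	1.21e-11	0.90	2.88e-5	0.86	1.59e-4	0.73	5.76e-3
Blue	bta-let-7a-5p	0.70	9.32e-9	0.81	7.38e-4	0.81	6.60e-4	0.70	8.10e-3
Blue	bta-miR-6522	0.68	3.17e-8	0.74	2.95e-3	0.84	2.87e-4	0.68	1.12e-2
Blue	bta-miR-100	0.68	2.69e-8	0.77	1.57e-3	0.68	7.88e-3	0.83	7.85e-4
Blue	bta-miR-374a	0.66	8.19e-8	0.77	1.72e-3	0.66	9.28e-3	0.80	1.46e-3
Blue	bta-miR-2284b	0.66	2.57e-7	0.66	9.38e-3	0.76	2.06e-3	0.76	3.07e-3
Blue	bta-miR-532	0.65	1.39e-7	0.83	4.06e-4	0.65	1.05e-2	0.71	7.23e-3
Blue	bta-miR-99b	0.64	1.01e-10	0.89	4.73e-5	0.64	1.28e-2	0.88	1.92e-4
Blue	bta-miR-23b-3p	0.62	2.65e-7	0.77	1.59e-3	0.62	1.66e-2	0.78	2.15e-3
Brown	bta-miR-484	0.78	1.28e-11	0.86	1.77e-4	0.78	1.27e-3	0.88	1.68e-4
Brown	bta-let-7d	0.76	1.24e-13	0.89	6.15e-5	0.93	6.37e-6	0.76	3.08e-3
Brown	bta-miR-429	0.74	8.47e-12	0.74	3.16e-3	0.87	1.13e-4	0.90	7.33e-5
Brown	bta-miR-885	0.73	2.27e-11	0.94	4.02e-6	0.77	1.57e-3	0.73	5.48e-3
Brown	bta-miR-26b	0.72	5.57e-9	0.74	2.98e-3	0.87	1.32e-4	0.72	6.31e-3
Brown	bta-miR-30c	0.71	4.04e-13	0.71	4.60e-3	0.93	5.77e-6	0.89	1.03e-4
Brown	bta-let-7g	0.70	2.80e-8	0.82	5.04e-4	0.70	5.68e-3	0.76	3.39e-3
Brown	bta-miR-29b	0.64	7.43e-6	0.68	7.75e-3	0.64	1.26e-2	0.68	1.03e-2
Brown	bta-miR-328	0.63	1.02e-6	0.63	1.39e-2	0.81	6.48e-4	0.64	1.67e-2
Brown	bta-miR-32	0.63	2.25e-7	0.63	1.43e-2	0.78	1.51e-3	0.78	2.35e-3
Brown	bta-miR-107	0.61	4.32e-7	0.61	1.78e-2	0.77	1.79e-3	0.77	2.66e-3
Brown	bta-let-7a-3p	0.60	2.14e-8	0.83	4.16e-4	0.82	5.65e-4	0.60	2.51e-2
Turquoise	bta-miR-16b	0.85	4.24e-12	0.86	1.93e-4	0.86	1.85e-4	0.85	4.94e-4
Turquoise	bta-miR-130a	0.84	1.36e-15	0.95	1.78e-6	0.88	6.75e-5	0.84	6.51e-4
Turquoise	bta-miR-142-5p	0.84	2.35e-13	0.88	7.90e-5	0.89	4.54e-5	0.84	6.66e-4
Turquoise	bta-miR-218	0.81	2.47e-14	0.85	2.40e-4	0.81	7.09e-4	0.95	3.45e-6
Turquoise	bta-miR-142-3p	0.80	9.04e-13	0.89	5.46e-5	0.88	7.17e-5	0.80	1.40e-3
Turquoise	bta-miR-195	0.77	1.20e-12	0.77	1.55e-3	0.80	8.03e-4	0.95	5.53e-6
Turquoise	bta-miR-497	0.75	5.71e-13	0.75	2.29e-3	0.85	2.52e-4	0.94	7.26e-6
Turquoise	bta-miR-16a	0.74	2.61e-11	0.82	5.21e-4	0.74	2.91e-3	0.92	3.83e-5
Turquoise	bta-miR-19b	0.70	1.90e-8	0.81	6.35e-4	0.70	5.93e-3	0.79	1.95e-3
Turquoise	bta-miR-3613	0.68	4.50e-7	0.76	2.12e-3	0.68	7.00e-3	0.72	6.31e-3
Turquoise	bta-miR-455-3p	0.67	1.02e-6	0.67	8.79e-3	0.70	5.94e-3	0.76	3.60e-3
Turquoise	bta-miR-15a	0.66	1.15e-7	0.85	2.03e-4	0.67	8.90e-3	0.66	1.30e-2
Turquoise	bta-miR-424-5p	0.65	1.45e-8	0.65	1.07e-2	0.89	5.66e-5	0.71	6.99e-3
Turquoise	bta-miR-106b	0.64	4.81e-12	0.89	5.64e-5	0.64	1.18e-2	0.93	2.05e-5
Turquoise	bta-miR-155	0.64	2.68e-7	0.83	4.77e-4	0.69	6.30e-3	0.64	1.68e-2
Turquoise	bta-miR-455-5p	0.63	7.14e-7	0.67	8.50e-3	0.63	1.35e-2	0.81	1.14e-3
Turquoise	bta-miR-93	0.63	5.83e-10	0.91	1.70e-5	0.63	1.37e-2	0.80	1.54e-3
Turquoise	bta-miR-199a-5p	0.61	5.53e-6	0.71	4.58e-3	0.68	7.05e-3	0.61	2.27e-2
Turquoise	bta-miR-99a-3p	0.60	7.73e-7	0.66	9.23e-3	0.60	1.94e-2	0.83	7.22e-4
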
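capacity
0.338936
0.431915
0.759932
0.724626
0.757583
0.811556
0.785339
0.783660
0.815627
0.847413
0.768007
0.843485
0.787408
0.849868
0.695970
0.842316
0.828689
0.580194
0.430681
0.742563
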